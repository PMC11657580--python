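"""End-to-end disease grading on a synthetic cohort.

Generates a two-class cohort of 30 closed surfaces (class 1 carries a
localized atrophy of 15% amplitude; ApoE-E4 is enriched in class 1), runs
the full pipeline -- Laplace-Beltrami eigenbases, pairwise functional maps
with ZoomOut, network pruning by 2-cycle consistency, consistent latent
basis, SPD shape-difference descriptors, Log-Euclidean features, population
graph -- and reports stratified Monte Carlo cross-validated metrics of the
transductive Chebyshev GCN.
"""

from shapegrade import synthetic_cohort
from shapegrade.pipeline import PipelineConfig, CohortStudy


def main():
    cohort = synthetic_cohort(n=30, effect_kind="bump", effect_size=0.15,
                              genus1_fraction=1 / 30, sides="right", seed=7)
    study = CohortStudy.from_cohort(cohort,
                                    PipelineConfig.desk(cv_draws=10, seed=7))
    network, clb = study.latent_basis("right")
    print(f"map network: k_used={network.k_used}, "
          f"{len(network.edges)} directed edges, "
          f"latent dimension m={clb.m}")
    result = study.evaluate()
    s = result.summary
    print(f"accuracy    {s['accuracy']['mean']:.3f} "
          f"+/- {s['accuracy']['std']:.3f}")
    print(f"precision   {s['precision']['mean']:.3f}")
    print(f"recall      {s['recall']['mean']:.3f}")
    print(f"specificity {s['specificity']['mean']:.3f}")
    print("\nMetrics are means over 10 stratified 70/30 train/test draws"
          "\nwith full retraining per draw; the class effect is strong, so"
          "\naccuracy should be well above the 0.5 chance level.")


if __name__ == "__main__":
    main()
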