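"""Why the blending weight matters: grading a purely extrinsic effect.

Generates a cohort whose class effect is a near-isometric bending (a
mirrored dome): intrinsic geometry is essentially unchanged, so purely
intrinsic descriptors (alpha = 0) cannot see the disease effect. Sweeping
the scale-free blending weight alpha (omega = alpha * l^2 with l the
bounding-box diagonal) shows the accuracy gain once extrinsic curvature
enters the descriptors. Maps and latent bases are computed once and reused
across alpha values.
"""

from shapegrade import synthetic_cohort
from shapegrade.pipeline import PipelineConfig, CohortStudy


def main():
    cohort = synthetic_cohort(n=30, effect_kind="bend", effect_size=0.15,
                              sides="right", seed=11)
    study = CohortStudy.from_cohort(
        cohort, PipelineConfig.desk(cv_draws=10, seed=11))
    alphas = [0.0, 2.0 ** -8, 2.0 ** -6, 2.0 ** -4]
    results = study.sweep_alpha(alphas)
    print(f"{'alpha':>10}  {'accuracy':>8}  {'std':>6}")
    for a in alphas:
        r = results[a]
        print(f"{a:10.6f}  {r.accuracy:8.3f}"
              f"  {r.summary['accuracy']['std']:6.3f}")
    print("\nalpha = 0 is blind to the bending (accuracy near the level"
          "\nthe phenotype graph alone provides); alpha > 0 recovers the"
          "\nclass effect from extrinsic curvature.")


if __name__ == "__main__":
    main()
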