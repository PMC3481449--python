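"""One-call experiment: preprocess -> sweep -> global and hub evaluation.

Runs the full pipeline on a synthetic instance and prints the report:
gain curves for the whole network and for the hub subnetwork (top 10%
most-connected genes and their interactions), plus the resolved
configuration that makes the run reproducible.
"""

from entgain import ExperimentConfig, InferenceConfig, SyntheticSpec, run_experiment

cfg = ExperimentConfig(
    synthetic=SyntheticSpec(
        n_genes=25, n_timepoints=40, noise=0.05,
        prior_fp_rate=0.2, prior_fn_rate=0.2, seed=2,
    ),
    inference=InferenceConfig(kmax=2),
    grid=(0.0, 0.5, 1.0),
    hub_fraction=0.10,
)
report = run_experiment(cfg)

for label, points in (("global", report.global_points), ("hub", report.hub_points)):
    print(f"\n{label} evaluation")
    for p in points:
        print(
            f"  w2={p.w2:<3g} PPV={p.metrics.ppv:.3f} "
            f"sensitivity={p.metrics.sensitivity:.3f} "
            f"similarity={p.metrics.similarity:.3f}"
        )

print("\nresolved defaults:", {
    k: report.resolved_config[k] for k in ("thresholds", "hub_fraction")
})
print()
print("The hub rows score only the best-connected part of the truth network;")
print("comparing them with the global rows shows whether prior knowledge")
print("helps more (or less) exactly where the network is densest.")
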