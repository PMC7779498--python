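"""The whole study in one call: run_study orchestrates every stage and
writes a machine-readable JSON report plus a Markdown summary.

Permutation counts are reduced here so the example runs in about a minute;
the defaults are 1000 permutations (10 000 for the party-within-gang tests).
"""

from convergekit import StudyConfig, run_study

cfg = StudyConfig(
    hwe_mc=10_000,
    pdfa_n_subsets=10,
    pdfa_n_permutations=49,
    n_permutations=199,
    n_permutations_party=499,
    seed=6,
    output_dir="scratch/example_report",
)
report = run_study(cfg)
print(report.summary_md())
print(f"\nfull report written to {cfg.output_dir}/ (report.json, report.md, matrices)")
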