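"""End-to-end study orchestration.

``run_study`` executes the full analysis in the study's canonical order:

1. locus screening (HWE + null alleles) → retained loci → Wang W matrix;
2. stepwise DFA on the call table → classification rates (resubstitution and
   leave-one-out, with the 100/g % chance level) → pairwise F → ln(1+F);
3. permuted DFA on balanced subsets;
4. the six dyadic tests: relatedness × gang, relatedness × party|gang,
   dissimilarity × gang, dissimilarity × party|gang, dissimilarity ×
   relatedness (Mantel), and the relatedness-quartile contrast — party-level
   tests use the restricted (within-gang) permutation scheme and a larger
   permutation count;
5. Cohen's d (same-group minus different-group convention) per contrast.

A single master seed deterministically spawns per-stage seeds, so every stage
is individually reproducible and the whole report is byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import CallFeatureTable, DyadicMatrix, GenotypeTable, SocialStructure
from .dfa import classify, dissimilarity_from_f, pairwise_f_matrix, stepwise_select
from .effects import cohens_d
from .mantel import PermutationScheme, categorical_mantel, mantel_test, quartile_contrast
from .pdfa import PdfaConfig, pdfa_test
from .relatedness import filter_loci, reports_frame, screen_loci, wang_pairwise
from .synthetic import (
    DEFAULT_GANG_PARTY_SIZES,
    FeatureSimConfig,
    PedigreeSimConfig,
    simulate_features,
    simulate_genotypes,
    build_structure,
)

logger = logging.getLogger("convergekit")

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_report"]


@dataclass
class StudyConfig:
    """Everything needed to run (or re-run) a study.

    Either all three input paths are set (ingest mode) or the simulation
    configs are used.  All permutation counts, thresholds and the master
    seed are recorded in the report.
    """

    # ingest mode
    features_path: str | None = None
    structure_path: str | None = None
    genotypes_path: str | None = None
    # simulation mode
    gang_party_sizes: list = field(default_factory=lambda: [list(x) for x in DEFAULT_GANG_PARTY_SIZES])
    feature_sim: dict = field(default_factory=dict)      # FeatureSimConfig overrides
    pedigree_sim: dict = field(default_factory=dict)     # PedigreeSimConfig overrides
    # analysis settings
    p_in: float = 0.05
    p_out: float = 0.10
    hwe_alpha: float = 0.05
    null_threshold: float = 0.05
    hwe_mc: int = 100_000
    pdfa_calls_per_class: int | None = None
    pdfa_n_subsets: int = 100
    pdfa_n_permutations: int = 1000
    pdfa_n_subsets_null: int = 1
    n_permutations: int = 1000
    n_permutations_party: int = 10_000
    quartile_q: float = 0.25
    seed: int = 0
    output_dir: str | None = None

    @property
    def ingest_mode(self) -> bool:
        paths = (self.features_path, self.structure_path, self.genotypes_path)
        if any(paths) and not all(paths):
            raise ValueError("ingest mode needs features, structure and genotype paths")
        if all(paths):
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            return True
        return False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        # json round trip normalises tuples to lists for safe_dump
        data = json.loads(json.dumps(dataclasses.asdict(self)))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class StudyReport:
    """Structured result of a full study run."""

    config: dict
    stage_seeds: dict
    counts: dict
    locus_screen: list
    dfa: dict
    pdfa: dict
    tests: dict
    effects: dict
    matrices: dict  # name -> {"ids": [...], "values": [[...]]}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(**d)

    def summary_md(self) -> str:
        c = self.counts
        lines = [
            "# Study report",
            "",
            f"- individuals: {c['n_individuals']} in {c['n_parties']} parties / {c['n_gangs']} gangs",
            f"- calls: {c['n_calls']} (per-subject range {c['calls_min']}-{c['calls_max']}, mean {c['calls_mean']:.1f})",
            f"- dyads: {c['n_dyads_total']} total, {c['n_dyads_within_gang']} within gangs",
            f"- loci: {c['n_loci']} genotyped, {c['n_loci_retained']} retained after screening",
            "",
            "## Individual acoustic signatures",
            f"- stepwise DFA selected {self.dfa['n_selected']} of {self.dfa['n_features']} features",
            f"- correct assignment: {self.dfa['percent_correct']:.1f}% (resubstitution), "
            f"{self.dfa['percent_correct_loo']:.1f}% (leave-one-out), chance {self.dfa['chance_percent']:.1f}%",
            f"- pDFA: {self.pdfa['observed']:.1f}% on {self.pdfa['n_subset_calls']} balanced calls "
            f"(chance {self.pdfa['chance_percent']:.1f}%), p = {self.pdfa['p_value']:.4g}",
            "",
            "## Dyadic tests",
        ]
        for name, t in self.tests.items():
            lines.append(
                f"- {name}: statistic = {t['observed']:.4g}, p = {t['p_value']:.4g} "
                f"({t['scheme']}, {t['n_permutations']} perms, {t['alternative']})"
            )
        lines.append("")
        lines.append("## Effect sizes (Cohen's d, same-group minus different-group)")
        for name, e in self.effects.items():
            lines.append(
                f"- {name}: d = {e['d']:.3f} [{e['ci_low']:.3f}, {e['ci_high']:.3f}] ({e['magnitude']})"
            )
        lines.append("")
        lines.append(
            "Note: dyadic values share individuals; CIs treat dyads as independent and are approximate."
        )
        return "\n".join(lines)


def _matrix_entry(m: DyadicMatrix) -> dict:
    return {"ids": list(m.ids), "kind": m.kind, "values": m.values.tolist()}


def _load_inputs(cfg: StudyConfig, seeds: dict):
    if cfg.ingest_mode:
        structure = SocialStructure.read_csv(cfg.structure_path)
        features = CallFeatureTable.read_csv(cfg.features_path)
        genotypes = GenotypeTable.read_csv(cfg.genotypes_path)
        return structure, features, genotypes
    structure = build_structure(cfg.gang_party_sizes)
    fcfg = FeatureSimConfig(**{**cfg.feature_sim, "seed": seeds["simulate_features"]})
    pcfg = PedigreeSimConfig(**{**cfg.pedigree_sim, "seed": seeds["simulate_genotypes"]})
    features = simulate_features(structure, fcfg)
    genotypes, _ = simulate_genotypes(structure, pcfg)
    return structure, features, genotypes


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the complete analysis; any stage failure aborts with the stage name."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(8)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            [
                "simulate_features",
                "simulate_genotypes",
                "hwe",
                "pdfa",
                "test_relatedness",
                "test_acoustics",
                "mantel_acoustic_genetic",
                "quartile",
            ],
            children,
        )
    }

    partial: dict = {}
    stage = "load_inputs"
    try:
        structure, features, genotypes = _load_inputs(cfg, seeds)
        counts_series = features.counts()
        n = structure.n
        gang_labels = structure.gang_labels()
        within_gang = int(
            sum(
                (gang_labels[:, None] == gang_labels[None, :])[np.triu_indices(n, k=1)]
            )
        )
        counts = {
            "n_individuals": n,
            "n_parties": len(structure.parties),
            "n_gangs": len(structure.gangs),
            "n_calls": int(counts_series.sum()),
            "calls_min": int(counts_series.min()),
            "calls_max": int(counts_series.max()),
            "calls_mean": float(counts_series.mean()),
            "n_dyads_total": n * (n - 1) // 2,
            "n_dyads_within_gang": within_gang,
            "n_loci": len(genotypes.loci),
        }

        stage = "locus_screening"
        reports = screen_loci(
            genotypes,
            hwe_alpha=cfg.hwe_alpha,
            null_threshold=cfg.null_threshold,
            hwe_mc=cfg.hwe_mc,
            seed=seeds["hwe"],
        )
        retained = filter_loci(reports)
        counts["n_loci_retained"] = len(retained)
        partial["locus_screen"] = reports_frame(reports).to_dict(orient="records")

        stage = "relatedness"
        W = wang_pairwise(genotypes.subset_loci(retained))

        stage = "stepwise_dfa"
        model = stepwise_select(features, p_in=cfg.p_in, p_out=cfg.p_out)
        if model.is_empty:
            raise ValueError("stepwise selection is empty; no acoustic signal to analyse")
        res_sub = classify(model, features, mode="resubstitution")
        res_loo = classify(model, features, mode="leave_one_out")
        fmat = pairwise_f_matrix(model)
        lnF = dissimilarity_from_f(fmat)
        lnF = lnF.reindex(structure.individuals)
        W = W.reindex(structure.individuals)
        partial["dfa"] = {
            "n_features": len(features.feature_names),
            "n_selected": model.p,
            "selected_features": list(model.selected_features),
            "trace": model.trace_frame().to_dict(orient="records"),
            "percent_correct": res_sub.percent_correct,
            "percent_correct_loo": res_loo.percent_correct,
            "chance_percent": res_sub.chance_percent,
            "n_calls_loo": res_loo.n_classified,
            "notes": list(model.notes),
        }

        stage = "pdfa"
        pcfg = PdfaConfig(
            calls_per_class=cfg.pdfa_calls_per_class,
            n_subsets=cfg.pdfa_n_subsets,
            n_permutations=cfg.pdfa_n_permutations,
            n_subsets_null=cfg.pdfa_n_subsets_null,
            p_in=cfg.p_in,
            p_out=cfg.p_out,
            seed=seeds["pdfa"],
        )
        pdfa_res = pdfa_test(features, pcfg)
        partial["pdfa"] = pdfa_res.to_dict()

        stage = "dyadic_tests"
        tests: dict = {}
        effects: dict = {}

        def free_scheme(seed_key, n_perm):
            return PermutationScheme(kind="free", n_permutations=n_perm, seed=seeds[seed_key])

        def gang_scheme(seed_key, n_perm):
            return PermutationScheme(
                kind="within_blocks",
                blocks=dict(structure.gang_of),
                n_permutations=n_perm,
                seed=seeds[seed_key],
            )

        contrasts = [
            ("relatedness_gang", W, "gang", free_scheme("test_relatedness", cfg.n_permutations), "less"),
            (
                "relatedness_party_within_gang",
                W,
                "party",
                gang_scheme("test_relatedness", cfg.n_permutations_party),
                "less",
            ),
            ("dissimilarity_gang", lnF, "gang", free_scheme("test_acoustics", cfg.n_permutations), "greater"),
            (
                "dissimilarity_party_within_gang",
                lnF,
                "party",
                gang_scheme("test_acoustics", cfg.n_permutations_party),
                "greater",
            ),
        ]
        for name, mat, level, scheme, alt in contrasts:
            con = categorical_mantel(mat, structure, level, scheme=scheme, alternative=alt)
            tests[name] = con.result.to_dict()
            tests[name]["n_same"] = con.n_a
            tests[name]["n_different"] = con.n_b
            effects[name] = cohens_d(con.values_a, con.values_b).to_dict()

        man = mantel_test(
            lnF,
            W,
            scheme=free_scheme("mantel_acoustic_genetic", cfg.n_permutations),
            alternative="two-sided",
        )
        tests["dissimilarity_vs_relatedness"] = man.to_dict()

        quart = quartile_contrast(
            W,
            lnF,
            q=cfg.quartile_q,
            n_permutations=cfg.n_permutations,
            seed=seeds["quartile"],
            alternative="less",
        )
        tests["quartile_contrast"] = quart.result.to_dict()
        tests["quartile_contrast"]["n_high"] = quart.n_b
        tests["quartile_contrast"]["n_low"] = quart.n_a
        effects["quartile_contrast"] = cohens_d(quart.values_b, quart.values_a).to_dict()

        report = StudyReport(
            config=dataclasses.asdict(cfg),
            stage_seeds=seeds,
            counts=counts,
            locus_screen=partial["locus_screen"],
            dfa=partial["dfa"],
            pdfa=partial["pdfa"],
            tests=tests,
            effects=effects,
            matrices={
                "dissimilarity_lnF": _matrix_entry(lnF),
                "relatedness_W": _matrix_entry(W),
            },
        )
        if cfg.output_dir:
            write_report(report, cfg.output_dir)
        return report
    except Exception as err:
        if cfg.output_dir and partial:
            try:
                outdir = Path(cfg.output_dir)
                outdir.mkdir(parents=True, exist_ok=True)
                (outdir / "partial_report.json").write_text(json.dumps(partial, indent=2, default=str))
            except OSError:
                logger.exception("could not preserve partial artifacts")
        raise RuntimeError(f"study failed at stage {stage!r}: {err}") from err


def write_report(report: StudyReport, outdir) -> None:
    """Write JSON + Markdown report and all matrices as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json(indent=2))
    (outdir / "report.md").write_text(report.summary_md() + "\n")
    for name, entry in report.matrices.items():
        m = DyadicMatrix(tuple(entry["ids"]), np.array(entry["values"]), entry["kind"])
        m.write_csv(outdir / f"{name}.csv")
    import pandas as pd

    pd.DataFrame(report.locus_screen).to_csv(outdir / "locus_screen.csv", index=False)
    pd.DataFrame(report.dfa["trace"]).to_csv(outdir / "dfa_trace.csv", index=False)
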