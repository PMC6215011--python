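"""End-to-end orchestration: simulate/ingest → filter → structure → scans →
replication → report, driven by a YAML config with fixed seeds.

Every stage is a pure function of (inputs, config, seed): rerunning the same
config yields a byte-identical output bundle.  Stage seeds are derived from
the top-level seed by fixed offsets and echoed in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotype import filter_loci, locus_summary, read_genepop, write_genepop
from .morphometrics import classify_morphs, wing_model
from .outlier import MCMCConfig, bayescan_fit, pcadapt_scan, wc_fst
from .replication import (
    make_designs,
    null_summary,
    overlap_report,
    run_replicated_scan,
)
from .structure import choose_k_bic, grm, grm_to_distance, nj_tree, pca, scree_k
from .synthetic import MorphParams, SimParams, simulate_genotypes, simulate_morphometrics

log = logging.getLogger("wingscan")

SCHEMA_VERSION = 1

# fixed per-stage seed offsets (top-level seed + offset)
_OFFSETS = {
    "simulate": 11,
    "morph": 13,
    "designs": 17,
    "scan": 19,
    "null": 23,
    "pcadapt": 29,
    "kmeans": 31,
}

FAST_PROFILE = {
    "n_loci": 2000,
    "mcmc": {"n_output": 400, "thinning": 2, "burn_in": 400,
             "n_pilot": 4, "pilot_length": 200},
    "n_random_runs": 2,
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``PipelineConfig.from_yaml``)."""

    seed: int = 0
    outdir: str = "wingscan_out"
    profile: str = "fast"  # "fast" | "paper"
    genepop_path: str | None = None
    morphometrics_path: str | None = None
    simulation: dict = field(default_factory=dict)
    simulate_morph: bool = True
    min_call_rate: float = 0.5
    min_maf: float = 0.05
    one_per_tag: bool = True
    mcmc: dict = field(default_factory=dict)
    q_thresholds: tuple[float, ...] = (0.2, 0.1, 0.05)
    n_random_runs: int = 20
    random_group_size: int = 34
    pca_k_max: int = 10
    scree_tau: float = 0.1
    bic_k_max: int = 6
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.profile not in ("fast", "paper"):
            raise ValueError("profile must be 'fast' or 'paper'")
        if (self.genepop_path is None) == (not self.simulation):
            # exactly one of input path / simulation block
            raise ValueError(
                "config must provide exactly one of genepop_path or a simulation block"
            )
        for t in (self.min_call_rate, self.min_maf, *self.q_thresholds):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold {t} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        if "q_thresholds" in raw:
            raw["q_thresholds"] = tuple(raw["q_thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def mcmc_config(self, seed: int) -> MCMCConfig:
        base = dict(FAST_PROFILE["mcmc"]) if self.profile == "fast" else {}
        base.update(self.mcmc)
        return MCMCConfig(seed=seed, **base)

    def sim_params(self) -> SimParams:
        sim = dict(self.simulation)
        sim.pop("morph", None)
        if self.profile == "fast":
            sim.setdefault("n_loci", FAST_PROFILE["n_loci"])
        sim.setdefault("seed", self.seed + _OFFSETS["simulate"])
        return SimParams(**sim)

    def effective_n_random_runs(self) -> int:
        if self.profile == "fast":
            return min(self.n_random_runs, FAST_PROFILE["n_random_runs"])
        return self.n_random_runs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns a summary dict (also written to disk)."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    manifest: dict = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": {k: seed + v for k, v in _OFFSETS.items()},
        "inputs": {},
    }
    summary_lines: list[str] = []

    # --- ingest or simulate ------------------------------------------------
    truth = None
    if cfg.genepop_path:
        gm = read_genepop(cfg.genepop_path)
        manifest["inputs"]["genepop"] = _sha256(Path(cfg.genepop_path))
        log.info("read %d individuals × %d loci from %s",
                 gm.n_individuals, gm.n_loci, cfg.genepop_path)
    else:
        params = cfg.sim_params()
        log.info("simulating genotypes with seed %d", params.seed)
        gm, truth = simulate_genotypes(params)
        truth.to_tsv(out / "sim_truth.tsv")
        write_genepop(gm, out / "simulated.genepop")

    morph_df = None
    if cfg.morphometrics_path:
        morph_df = pd.read_csv(cfg.morphometrics_path)
        manifest["inputs"]["morphometrics"] = _sha256(Path(cfg.morphometrics_path))
    elif truth is not None and cfg.simulate_morph:
        levels = gm.group_levels
        n1 = gm.group_labels.count(levels[0])
        n2 = gm.group_labels.count(levels[1])
        morph_df = simulate_morphometrics(
            n1, n2, MorphParams(), seed=seed + _OFFSETS["morph"]
        )
        morph_df.to_csv(out / "morphometrics.csv", index=False)

    # --- filtering and summaries -------------------------------------------
    filtered = filter_loci(gm, cfg.min_call_rate, cfg.min_maf, cfg.one_per_tag)
    log.info("filtering kept %d of %d loci", filtered.n_loci, gm.n_loci)
    stats = locus_summary(filtered)
    _write_tsv(stats, out / "locus_summary.tsv")
    write_genepop(filtered, out / "filtered.genepop")
    summary_lines.append(
        f"Loci: {gm.n_loci} input, {filtered.n_loci} after filtering "
        f"(call rate ≥ {cfg.min_call_rate}, MAF ≥ {cfg.min_maf})."
    )
    summary_lines.append(
        f"Observed heterozygosity mean {stats['ho'].mean():.3f} "
        f"(sd {stats['ho'].std(ddof=1):.3f}); expected {stats['he'].mean():.3f} "
        f"(sd {stats['he'].std(ddof=1):.3f})."
    )

    # --- population structure ----------------------------------------------
    # full score space for BIC clustering; the scree rule reads the leading
    # k_max eigenvalues (the visible part of the scree plot)
    k_full = min(filtered.n_individuals - 1, filtered.n_loci)
    k_max = min(cfg.pca_k_max, k_full)
    pca_res = pca(filtered, k_max=k_full)
    _write_tsv(
        pd.DataFrame(
            pca_res.scores[:, :k_max],
            index=pd.Index(filtered.individual_ids, name="individual_id"),
            columns=[f"PC{i + 1}" for i in range(k_max)],
        ),
        out / "pc_scores.tsv",
    )
    _write_tsv(
        pd.DataFrame({"eigenvalue": pca_res.eigenvalues}),
        out / "eigenvalues.tsv",
        index=False,
    )
    g = grm(filtered)
    _write_tsv(
        pd.DataFrame(g, index=filtered.individual_ids, columns=filtered.individual_ids),
        out / "grm.tsv",
    )
    newick = nj_tree(grm_to_distance(g), filtered.individual_ids)
    (out / "relatedness_nj.nwk").write_text(newick + "\n")
    k_bic = choose_k_bic(pca_res, k_max=min(cfg.bic_k_max, filtered.n_individuals),
                         seed=seed + _OFFSETS["kmeans"])  # full score space
    summary_lines.append(f"BIC-optimal number of clusters: {k_bic}.")

    # --- scans ---------------------------------------------------------------
    theta = wc_fst(filtered)
    k_scree = scree_k(pca_res.eigenvalues[:k_max], tau=cfg.scree_tau)
    k_scree = min(k_scree, max(k_max - 1, 1))
    pc_scan = pcadapt_scan(filtered, K=k_scree, seed=seed + _OFFSETS["pcadapt"])
    summary_lines.append(
        f"PCA scan: K = {k_scree} (scree rule), genomic inflation λ = "
        f"{pc_scan.attrs['lambda']:.3f}."
    )

    labels = dict(zip(filtered.individual_ids, filtered.group_labels))
    designs = make_designs(labels, "balanced_split", seed=seed + _OFFSETS["designs"])
    scan_cfg = cfg.mcmc_config(seed + _OFFSETS["scan"])
    log.info("running %d balanced scans (chain seed %d)", len(designs), scan_cfg.seed)
    balanced = run_replicated_scan(filtered, designs, scan_cfg,
                                   cfg.min_call_rate, cfg.min_maf)
    report = overlap_report(balanced, cfg.q_thresholds, L=filtered.n_loci)

    n_runs = cfg.effective_n_random_runs()
    null_designs = make_designs(
        labels, "randomized", n_random_runs=n_runs,
        random_group_size=min(cfg.random_group_size, filtered.n_individuals // 2),
        seed=seed + _OFFSETS["designs"] + 1,
    )
    null_cfg = cfg.mcmc_config(seed + _OFFSETS["null"])
    log.info("running %d randomized-null scans", len(null_designs))
    nulls = run_replicated_scan(filtered, null_designs, null_cfg,
                                cfg.min_call_rate, cfg.min_maf)
    report.null_mean_count, report.null_max_count, report.null_min_q = null_summary(
        nulls, max(cfg.q_thresholds)
    )

    # per-locus results table
    scan_table = pd.DataFrame(
        {
            "wc_fst": theta,
            "posterior_prob_run1": balanced[0].table["posterior_prob"].reindex(filtered.locus_ids),
            "q_bayes_run1": balanced[0].table["q_value"].reindex(filtered.locus_ids),
            "posterior_prob_run2": balanced[1].table["posterior_prob"].reindex(filtered.locus_ids),
            "q_bayes_run2": balanced[1].table["q_value"].reindex(filtered.locus_ids),
            "stat_pca": pc_scan["stat"],
            "p_pca": pc_scan["p_value"],
            "q_pca": pc_scan["q_value"],
        },
        index=pd.Index(filtered.locus_ids, name="locus_id"),
    )
    _write_tsv(scan_table, out / "scan_results.tsv")
    for run, res in zip(("run1", "run2"), balanced):
        _write_tsv(res.diagnostics, out / f"chain_diagnostics_{run}.tsv", index=False)

    # replication report TSV + design JSON
    rep_rows = []
    for t in cfg.q_thresholds:
        s1, s2 = report.outliers_per_run[t]
        rep_rows.append(
            {
                "q_threshold": t,
                "run1_outliers": len(s1),
                "run2_outliers": len(s2),
                "shared": len(report.shared_loci[t]),
                "overlap_p": report.overlap_p[t],
            }
        )
    rep_df = pd.DataFrame(rep_rows)
    rep_df["expected_overlap"] = report.expected_overlap
    rep_df["top_locus_run1"], rep_df["top_locus_run2"] = report.top_locus_per_run
    rep_df["null_mean"] = report.null_mean_count
    rep_df["null_max"] = report.null_max_count
    rep_df["null_min_q"] = report.null_min_q
    _write_tsv(rep_df, out / "replication_report.tsv", index=False)
    (out / "designs.json").write_text(
        json.dumps(
            [dataclasses.asdict(d) for d in designs + null_designs], indent=2
        )
        + "\n"
    )

    # structure re-check on the putatively neutral set (outliers removed),
    # the dataset the no-structure conclusion is properly stated on
    t0 = max(cfg.q_thresholds)
    flagged = set().union(*report.outliers_per_run[t0])
    neutral_ids = [l for l in filtered.locus_ids if l not in flagged]
    k_bic_neutral = k_bic
    if 2 <= len(neutral_ids) < filtered.n_loci:
        neutral_pca = pca(
            filtered.subset_loci(neutral_ids),
            k_max=min(k_full, len(neutral_ids)),
        )
        k_bic_neutral = choose_k_bic(
            neutral_pca, k_max=min(cfg.bic_k_max, filtered.n_individuals),
            seed=seed + _OFFSETS["kmeans"],
        )
    summary_lines.append(
        f"BIC-optimal clusters on the putatively neutral set "
        f"({len(neutral_ids)} loci): {k_bic_neutral}."
    )

    summary_lines.append(
        f"Balanced scans: {len(report.outliers_per_run[t0][0])} and "
        f"{len(report.outliers_per_run[t0][1])} outliers at q ≤ {t0}; "
        f"{len(report.shared_loci[t0])} shared "
        f"(expected {report.expected_overlap:.2f} under independence, "
        f"P = {report.overlap_p[t0]:.3g})."
    )
    summary_lines.append(
        f"Top locus per run: {report.top_locus_per_run[0]} / "
        f"{report.top_locus_per_run[1]}"
        + (" (coincide)" if report.top_locus_coincides else " (differ)")
    )
    summary_lines.append(
        f"Randomized nulls ({len(nulls)} runs): mean {report.null_mean_count:.1f} "
        f"outliers at q ≤ {t0}, max {report.null_max_count}, "
        f"min q {report.null_min_q:.3g}."
    )
    if truth is not None:
        planted = set(truth.assoc_locus_ids) & set(filtered.locus_ids)
        shared = report.shared_loci[t0]
        summary_lines.append(
            f"Ground truth: {len(planted)} planted loci retained; "
            f"{len(planted & shared)} among the shared outliers."
        )

    # --- morphometrics -------------------------------------------------------
    if morph_df is not None:
        classification = classify_morphs(morph_df)
        labeled = morph_df.assign(class_label=classification.labels)
        labeled.to_csv(out / "morphometrics_classified.csv", index=False)
        summary_lines.append(
            f"Morph classification: dimorphism "
            f"{'detected' if classification.dimorphic else 'not detected'}; "
            "class ratio means "
            + ", ".join(
                f"{idx} {row.ratio_mean:.2f}±{row.ratio_sd:.2f}"
                for idx, row in classification.class_stats.iterrows()
            )
            + f"; threshold {classification.threshold:.2f}."
        )
        if classification.dimorphic:
            coef = wing_model(labeled)
            _write_tsv(coef, out / "wing_model.tsv")

    summary = "\n".join(summary_lines) + "\n"
    (out / "summary.txt").write_text(summary)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete; outputs in %s", out)
    return {
        "summary": summary,
        "report": report,
        "k_bic": k_bic,
        "k_scree": k_scree,
        "n_loci_filtered": filtered.n_loci,
        "outdir": str(out),
    }
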