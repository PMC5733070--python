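"""End-to-end pipeline orchestration, configuration, and figure generation.

A run is driven by a single declarative config (YAML-compatible dict).
Every numeric table written into the run directory is stamped with the
config hash and seed on its first line, so a rerun with the same config is
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from haplopaint.data_model import (
    GeneticMap,
    GenotypeMatrix,
    PeriodBounds,
    SampleMetadata,
    ValidationError,
    assign_periods,
    write_genotypes,
    write_map,
    write_metadata,
)
from haplopaint import genotype_qc, synthetic_data
from haplopaint.diversity_ld_ne import (
    background_threshold,
    decay_curve,
    diversity_summary,
    ld_block_size,
    ne_ld,
    pairwise_r2,
    window_spectra,
)
from haplopaint.painting import (
    paint_panel,
    detect_deviant_regions,
    summarize_ancestry,
)
from haplopaint.painting.summary import regions_to_frame
from haplopaint.popgen_stats import average_pairwise_fst, amova, wc_fst

log = logging.getLogger("haplopaint.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "qc": True,
        "diversity": True,
        "ld": True,
        "popgen": True,
        "painting": True,
    },
    "simulate": {
        "n_subpops": 4,
        "fst": 0.2,
        "n_snps": 1000,
        "n_chromosomes": 5,
        "map_length_cm": 150.0,
        "n_samples": 30,
        "n_generations": 20,
        "recipients": {
            "proportions": {1: 0.5, 2: 0.5},
            "breakpoint_rate": 0.0333,
            "n_recipients": 20,
            "epsilon": 0.002,
        },
    },
    "qc": {"max_missing": 0.5, "min_maf": 0.05, "impute": True},
    "diversity": {"window": 15, "step": 1},
    "ld": {"bin_cm": 1.0, "quantile": 0.99, "max_inter_pairs": 200000, "min_complete": 10},
    "periods": {"cut1": 1920, "cut2": 1970},
    "painting": {
        "rho": 0.1,
        "em_steps": 20,
        "replicates": 100,
        "exclude_subpops": [],
        "focal_subpop": None,
        "min_snps": 3,
        "dominance_frac": 0.5,
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, stamp: str, index: bool = False, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=index, sep=sep)


def read_table(path: str | Path, sep: str = ",", **kw) -> pd.DataFrame:
    """Read a pipeline table, skipping the stamp line."""
    return pd.read_csv(path, comment="#", sep=sep, **kw)


def run_pipeline(config: Mapping, outdir: str | Path) -> Path:
    """Execute enabled stages in dependency order into ``outdir``.

    Returns the run directory.  On stage failure, partial outputs are kept
    and a :class:`PipelineError` naming the stage is raised.
    """
    cfg = _deep_merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stamp = f"config_hash={config_hash(cfg)} seed={seed}"
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stages = cfg["stages"]
    state: dict[str, Any] = {}
    try:
        if stages.get("simulate", True):
            _stage_simulate(cfg, outdir, stamp, state, seed)
        if stages.get("qc", True):
            _run_stage("qc", _stage_qc, cfg, outdir, stamp, state)
        if stages.get("diversity", True):
            _run_stage("diversity", _stage_diversity, cfg, outdir, stamp, state)
        if stages.get("ld", True):
            _run_stage("ld", _stage_ld, cfg, outdir, stamp, state)
        if stages.get("popgen", True):
            _run_stage("popgen", _stage_popgen, cfg, outdir, stamp, state)
        if stages.get("painting", True):
            _run_stage("painting", _stage_painting, cfg, outdir, stamp, state)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _run_stage(name, fn, cfg, outdir, stamp, state) -> None:
    log.info("stage %s: start", name)
    try:
        fn(cfg, outdir, stamp, state)
    except Exception as exc:
        log.error("stage %s: FAILED: %s", name, exc)
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done", name)


def _stage_simulate(cfg, outdir, stamp, state, seed) -> None:
    try:
        sc = cfg["simulate"]
        dcfg = synthetic_data.DonorSimConfig(
            n_subpops=int(sc["n_subpops"]),
            fst=float(sc["fst"]),
            n_snps=int(sc["n_snps"]),
            n_chromosomes=int(sc["n_chromosomes"]),
            map_length_cm=float(sc["map_length_cm"]),
            n_samples=int(sc["n_samples"]),
            n_generations=int(sc["n_generations"]),
            seed=seed,
        )
        donors, gmap, meta = synthetic_data.simulate_donor_pops(dcfg)
        rc = sc["recipients"]
        props = {int(k): float(v) for k, v in rc["proportions"].items()}
        recipients, truth = synthetic_data.simulate_mosaic_recipients(
            donors,
            gmap,
            meta,
            props,
            breakpoint_rate=float(rc["breakpoint_rate"]),
            n_recipients=int(rc["n_recipients"]),
            seed=seed + 1,
            epsilon=float(rc.get("epsilon", 0.002)),
        )
        rng = np.random.default_rng(seed + 2)
        years = rng.integers(1850, 2011, size=recipients.n_samples)
        states = rng.choice(["NSW", "QLD", "VIC", "SA", "WA"], size=recipients.n_samples)
        rmeta = synthetic_data.recipient_metadata(recipients.sample_ids, years, states)
        bounds = PeriodBounds(int(cfg["periods"]["cut1"]), int(cfg["periods"]["cut2"]))
        full_meta = SampleMetadata(pd.concat([meta.table, rmeta.table]))
        full_meta = assign_periods(full_meta, bounds)
        write_genotypes(donors, outdir / "donors.csv")
        write_genotypes(recipients, outdir / "recipients.csv")
        write_map(gmap, outdir / "map.tsv")
        write_metadata(full_meta, outdir / "metadata.csv")
        truth_payload = {
            "proportions": {
                r: {str(k): float(v) for k, v in row.items()}
                for r, row in truth.proportions.iterrows()
            },
            "segments": truth.segments.to_dict(orient="records"),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_payload, fh, indent=1, sort_keys=True)
        state.update(
            donors=donors, recipients=recipients, gmap=gmap, metadata=full_meta, truth=truth
        )
    except Exception as exc:
        log.error("stage simulate: FAILED: %s", exc)
        raise PipelineError("simulate", exc) from exc


def _stage_qc(cfg, outdir, stamp, state) -> None:
    qc = cfg["qc"]
    donors, recipients = state["donors"], state["recipients"]
    donors = genotype_qc.filter_missing(donors, float(qc["max_missing"]))
    recipients = genotype_qc.filter_missing(recipients, float(qc["max_missing"]))
    if qc.get("impute", True):
        if donors.missing_mask.any():
            donors = genotype_qc.impute_ldknni(donors)
        if recipients.missing_mask.any():
            recipients = genotype_qc.impute_ldknni(recipients)
    recipients = genotype_qc.filter_maf(recipients, float(qc["min_maf"]))
    donors, recipients = genotype_qc.intersect_snps(donors, recipients)
    write_genotypes(donors, outdir / "donors_qc.csv")
    write_genotypes(recipients, outdir / "recipients_qc.csv")
    state.update(donors=donors, recipients=recipients)


def _periods_of(state) -> pd.Series:
    meta = state["metadata"].table
    rec = meta[meta["role"] == "recipient"]
    return rec["period"].dropna()


def _stage_diversity(cfg, outdir, stamp, state) -> None:
    dv = cfg["diversity"]
    recipients, gmap = state["recipients"], state["gmap"]
    periods = _periods_of(state)
    rows = []
    for period, ids in periods.groupby(periods):
        sub = recipients.take_samples([s for s in ids.index if s in set(recipients.sample_ids)])
        spectra = window_spectra(sub, gmap, w=int(dv["window"]), step=int(dv["step"]))
        if not spectra:
            continue
        summ = diversity_summary(spectra)
        rows.append({"group": f"period{period}", **summ})
    spectra = window_spectra(recipients, gmap, w=int(dv["window"]), step=int(dv["step"]))
    if spectra:
        rows.append({"group": "all", **diversity_summary(spectra)})
    if not rows:
        raise ValidationError(
            f"no chromosome has >= {dv['window']} SNPs; reduce the window size"
        )
    _write_table(pd.DataFrame(rows), outdir / "diversity.csv", stamp)


def _stage_ld(cfg, outdir, stamp, state) -> None:
    ld = cfg["ld"]
    recipients, gmap = state["recipients"], state["gmap"]
    seed = int(cfg["seed"])
    mc = int(ld.get("min_complete", 10))
    intra = pairwise_r2(recipients, gmap, "intra_chrom", min_complete=mc)
    inter = pairwise_r2(
        recipients, gmap, "inter_chrom",
        max_pairs=int(ld["max_inter_pairs"]), seed=seed, min_complete=mc,
    )
    thr = background_threshold(inter["r2"], float(ld["quantile"]))
    curve = decay_curve(intra, bin_cm=float(ld["bin_cm"]))
    block = ld_block_size(intra, thr, bin_cm=float(ld["bin_cm"]), min_pairs=1)
    ne = ne_ld(recipients, gmap, seed=seed, method="first_order")
    _write_table(curve, outdir / "ld_decay.csv", stamp)
    summary = pd.DataFrame(
        [
            {
                "background_r2": thr,
                "block_cm": block["block_cm"],
                "crossed": block["crossed"],
                "ne_estimate": ne.estimate,
                "ne_sample_size": ne.sample_size,
                "mean_r2": ne.mean_r2,
            }
        ]
    )
    _write_table(summary, outdir / "ld_summary.csv", stamp)
    state.update(background_r2=thr)


def _stage_popgen(cfg, outdir, stamp, state) -> None:
    recipients = state["recipients"]
    periods = _periods_of(state)
    ids = [s for s in recipients.sample_ids if s in periods.index]
    labels = [int(periods[s]) for s in ids]
    sub = recipients.take_samples(ids)
    rows = []
    if len(set(labels)) >= 2:
        res = wc_fst(sub, labels)
        rows.append({"comparison": "all_periods", "fst": res.estimate})
        from haplopaint.popgen_stats import pairwise_fst

        for _, r in pairwise_fst(sub, labels).iterrows():
            rows.append(
                {"comparison": f"period{r.pop1}_vs_period{r.pop2}", "fst": r.fst}
            )
        am = amova(sub, labels, n_perm=0)
        for level, pct in am.percentages.items():
            if pct is not None:
                rows.append({"comparison": f"amova_pct_{level}", "fst": pct})
    donors = state["donors"]
    meta = state["metadata"]
    donor_tbl = meta.donors()
    dids = [s for s in donors.sample_ids if s in donor_tbl.index]
    dlabels = [int(donor_tbl.loc[s, "subpop_id"]) for s in dids]
    rows.append(
        {
            "comparison": "avg_pairwise_donor_fst",
            "fst": average_pairwise_fst(donors.take_samples(dids), dlabels),
        }
    )
    _write_table(pd.DataFrame(rows), outdir / "fst.csv", stamp)


def _stage_painting(cfg, outdir, stamp, state) -> None:
    pc = cfg["painting"]
    donors, recipients = state["donors"], state["recipients"]
    gmap, meta = state["gmap"], state["metadata"]
    result = paint_panel(
        donors,
        recipients,
        gmap,
        meta,
        rho=float(pc["rho"]),
        n_em_steps=int(pc["em_steps"]),
        n_replicates=int(pc["replicates"]),
        seed=int(cfg["seed"]) + 10,
        exclude_pops=[int(p) for p in pc.get("exclude_subpops", [])],
    )
    cons = result.consensus
    _write_table(cons.to_frame(), outdir / "consensus.tsv", stamp, sep="\t")
    summ = summarize_ancestry(cons, meta, group_by="recipient")
    _write_table(
        summ.recipient_proportions, outdir / "recipient_proportions.csv", stamp, index=True
    )
    try:
        by_period = summarize_ancestry(cons, meta, group_by="period")
        _write_table(
            by_period.group_proportions, outdir / "period_proportions.csv", stamp, index=True
        )
        for gname, prof in by_period.locus_profiles.items():
            _write_table(
                prof, outdir / f"locus_profile_period{gname}.csv", stamp, index=True
            )
        focal = pc.get("focal_subpop")
        if focal is not None:
            regions = []
            for gname, prof in by_period.locus_profiles.items():
                regs = detect_deviant_regions(
                    prof,
                    cons.chrom,
                    cons.cm,
                    int(focal),
                    min_snps=int(pc["min_snps"]),
                    dominance_frac=float(pc["dominance_frac"]),
                )
                df = regions_to_frame(regs)
                if not df.empty:
                    df.insert(0, "group", f"period{gname}")
                    regions.append(df)
            out = (
                pd.concat(regions, ignore_index=True)
                if regions
                else pd.DataFrame(
                    columns=[
                        "group", "chrom", "start_cm", "end_cm", "start_snp",
                        "end_snp", "n_snps", "dominant_subpops", "mean_focal_fraction",
                    ]
                )
            )
            _write_table(out, outdir / "deviant_regions.tsv", stamp, sep="\t")
    except Exception:
        # period metadata may be absent in reduced runs; recipient-level
        # outputs above are still written
        log.warning("period-level painting summaries skipped", exc_info=True)
    state.update(consensus=cons)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(run_dir: str | Path) -> list[Path]:
    """Generate basic plots from a completed run directory."""
    run_dir = Path(run_dir)
    out: list[Path] = []
    decay_path = run_dir / "ld_decay.csv"
    if decay_path.exists():
        curve = read_table(decay_path)
        summary = read_table(run_dir / "ld_summary.csv")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["bin_mid_cm"], curve["mean_r2"], lw=1, label="mean $r^2$")
        ax.plot(curve["bin_mid_cm"], curve["smoothed_r2"], lw=2, label="smoothed")
        ax.axhline(summary["background_r2"].iloc[0], color="red", ls="--", label="background")
        ax.set_xlabel("distance (cM)")
        ax.set_ylabel("$r^2$")
        ax.legend()
        fig.tight_layout()
        p = run_dir / "fig_ld_decay.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)
    profiles = sorted(run_dir.glob("locus_profile_*.csv"))
    if profiles:
        fig, axes = plt.subplots(len(profiles), 1, figsize=(8, 2.2 * len(profiles)), squeeze=False)
        for ax, path in zip(axes[:, 0], profiles):
            prof = read_table(path, index_col=0)
            bottom = np.zeros(len(prof))
            xs = np.arange(len(prof))
            for col in prof.columns:
                ax.bar(xs, prof[col], bottom=bottom, width=1.0, label=str(col))
                bottom += prof[col].to_numpy()
            ax.set_ylim(0, 1)
            ax.set_title(path.stem.replace("locus_profile_", ""))
            ax.set_xticks([])
        axes[0, 0].legend(fontsize=6, ncol=6)
        fig.tight_layout()
        p = run_dir / "fig_ancestry_profiles.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        out.append(p)
    props_path = run_dir / "recipient_proportions.csv"
    meta_path = run_dir / "metadata.csv"
    if props_path.exists() and meta_path.exists():
        props = read_table(props_path, index_col=0)
        meta = pd.read_csv(meta_path, index_col=0)
        periods = meta.loc[meta["role"] == "recipient", "period"]
        fig, ax = plt.subplots(figsize=(7, 4))
        data, labels = [], []
        for period in sorted(periods.dropna().unique()):
            members = [s for s in props.index if periods.get(s) == period]
            for pop in props.columns:
                data.append(props.loc[members, pop].to_numpy())
                labels.append(f"p{int(period)}:{pop}")
        if data:
            ax.boxplot(data, tick_labels=labels)
            ax.set_ylabel("ancestry proportion")
            ax.tick_params(axis="x", labelsize=6, rotation=90)
            fig.tight_layout()
            p = run_dir / "fig_contributions.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            out.append(p)
        else:
            plt.close(fig)
    return out
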