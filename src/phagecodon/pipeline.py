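"""End-to-end orchestration: metrics → distances → statistics ledger.

``run_all`` (or the CLI verbs wrapping the individual stages) takes either
real inputs (CDS FASTA + host codon-usage table + similarity hits +
annotation TSV) or a synthetic-data configuration, and emits per-gene metric
tables, per-lifestyle heterogeneity summaries, and a statistics bundle with
seven blocks: (a) genome-size Kruskal-Wallis + Dunn with rank effect sizes,
(b) per-metric omnibus tests with epsilon-squared labels, (c) pairwise
Mann-Whitney contrasts with Holm correction and Cliff's delta, (d) Spearman /
bootstrap-CI / BH correlation matrices plus GC-controlled partial Spearman,
(e) functional-category analyses (Scheirer-Ray-Hare, within-lifestyle and
within-category contrasts), (f) PERMANOVA + PERMDISP per lifestyle pair, and
(g) genome size vs tRNA count correlation. Every p-value row names its
correction; every stochastic block records its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import distance as dist
from . import io as pio
from . import simulate as sim
from . import stats as pstats
from .codon import adaptiveness_weights, gene_metrics_table
from .errors import ValidationError

logger = logging.getLogger(__name__)

METRICS = ("nt", "gc", "gc1", "gc2", "gc3", "cai", "nc")
LIFESTYLE_ORDER = ("virulent", "temperate", "prophage")


@dataclass
class RunConfig:
    """Pipeline configuration. A seed is required whenever any stochastic
    block (simulation, bootstrap, PERMANOVA) is enabled."""

    seed: int
    out_dir: str | Path | None = None
    # inputs: either simulate, or explicit paths
    simulate: bool = True
    sim_config: sim.SimConfig | None = None
    fasta: str | Path | None = None
    codon_table: str | Path | None = None
    codon_table_dialect: str = "kazusa"
    hits: str | Path | None = None
    annotation: str | Path | None = None
    # analysis toggles
    do_genome_size: bool = True
    do_metric_kw: bool = True
    do_pairwise: bool = True
    do_correlations: bool = True
    do_functional: bool = True
    do_permanova: bool = True
    do_trna: bool = True
    # block parameters
    n_perm: int = 999
    permanova_subsample_n: int | None = None  # default: smallest group size
    bootstrap_B: int = 1000
    category_unit: str = "genome_median"  # or "gene"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required")
        if self.category_unit not in ("genome_median", "gene"):
            raise ValidationError("category_unit must be 'genome_median' or 'gene'")
        if self.simulate and self.sim_config is None:
            self.sim_config = sim.SimConfig(seed=self.seed)


# ---------------------------------------------------------------------------
# input loading


def load_inputs(config: RunConfig):
    """(records, annotation rows, host table, hits) from files or simulation."""
    if config.simulate:
        table = sim.synthetic_host_table()
        records, rows = sim.generate_dataset(config.sim_config, table)
        hits = sim.generate_similarity_table(config.sim_config)
        return records, rows, table, hits
    missing = [
        name
        for name, p in (
            ("fasta", config.fasta),
            ("codon_table", config.codon_table),
            ("annotation", config.annotation),
        )
        if p is None
    ]
    if missing:
        raise ValidationError(
            f"missing inputs: {missing}; provide paths or set simulate=True"
        )
    records = pio.read_fasta_cds(config.fasta)
    rows = pio.read_annotation_table(config.annotation)
    by_gene = {r.gene_id: r for r in rows}
    joined = []
    for rec in records:
        ann = by_gene.get(rec.gene_id)
        if ann is None:
            raise ValidationError(f"gene {rec.gene_id!r} absent from annotation table")
        joined.append(
            dataclasses.replace(
                rec,
                genome_id=ann.genome_id,
                lifestyle=ann.lifestyle,
                product=ann.product or rec.product,
            )
        )
    table = pio.read_codon_usage_table(config.codon_table, config.codon_table_dialect)
    hits = pio.read_directional_hits(config.hits) if config.hits else []
    return joined, rows, table, hits


# ---------------------------------------------------------------------------
# stage: metrics

_DESCRIBE_COLS = ("mean", "sd", "min", "max", "p10", "p25", "p50", "p75", "p90", "iqr")


def describe(values: np.ndarray) -> dict[str, float]:
    """Descriptive block: mean, SD (n-1), min, max, P10-P90, IQR (Q3-Q1)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "p10": float(q[0]),
        "p25": float(q[1]),
        "p50": float(q[2]),
        "p75": float(q[3]),
        "p90": float(q[4]),
        "iqr": float(q[3] - q[1]),
    }


def lifestyle_summaries(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-lifestyle descriptive statistics for each metric (one row each)."""
    rows = []
    for metric in METRICS:
        for lifestyle, sub in metrics.groupby("lifestyle", observed=True):
            rows.append(
                {"metric": metric, "lifestyle": lifestyle}
                | describe(sub[metric].to_numpy(dtype=float))
            )
    return pd.DataFrame(rows)


def run_metrics(config: RunConfig, inputs=None):
    """Per-gene metric table plus per-lifestyle descriptive summary blocks."""
    records, rows, table, _ = inputs if inputs is not None else load_inputs(config)
    weights = adaptiveness_weights(table)
    metrics = gene_metrics_table(records, weights)
    summaries = lifestyle_summaries(metrics)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_table(metrics, out / "gene_metrics.tsv")
        pio.write_table(summaries, out / "lifestyle_summaries.tsv")
    return metrics, summaries


# ---------------------------------------------------------------------------
# stage: distances


def run_distance(config: RunConfig, inputs=None):
    """Per-lifestyle pair tables and dual heterogeneity summaries."""
    records, rows, _, hits = inputs if inputs is not None else load_inputs(config)
    genome_lifestyle: dict[str, str] = {}
    for r in rows:
        genome_lifestyle[r.genome_id] = r.lifestyle
    hit_genomes = {h.query_id for h in hits} | {h.subject_id for h in hits}
    unknown = sorted(hit_genomes - set(genome_lifestyle))
    if unknown:
        raise ValidationError(f"hit genomes absent from annotation: {unknown}")
    pair_tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    for lifestyle in sorted({r.lifestyle for r in rows}):
        ids = sorted(g for g, ls in genome_lifestyle.items() if ls == lifestyle)
        group_hits = [
            h for h in hits if genome_lifestyle[h.query_id] == lifestyle
            and genome_lifestyle[h.subject_id] == lifestyle
        ]
        pairs = dist.pair_from_hits(group_hits, ids)
        pair_tables[lifestyle] = dist.pairs_frame(pairs)
        entry = {"all_pairs": dist.summary_dict(dist.summarize(pairs, "all_pairs"))}
        if any(not p.nss for p in pairs):
            entry["valid_only"] = dist.summary_dict(dist.summarize(pairs, "valid_only"))
        summaries[lifestyle] = entry
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for lifestyle, df in pair_tables.items():
            pio.write_table(df, out / f"pairs_{lifestyle}.tsv")
        (out / "heterogeneity_summaries.json").write_text(
            json.dumps(summaries, indent=2)
        )
    return pair_tables, summaries


# ---------------------------------------------------------------------------
# stage: statistics ledger


def _contrast_dict(c: pstats.PairwiseContrast, correction_note: str) -> dict:
    return {
        "group_1": c.group_1,
        "group_2": c.group_2,
        "mean_rank_1": c.mean_rank_1,
        "mean_rank_2": c.mean_rank_2,
        "z": c.z,
        "p_raw": c.p_raw,
        "p_bonferroni": c.p_bonferroni,
        "p_holm": c.p_holm,
        "cliffs_delta": c.cliffs_delta,
        "magnitude": c.magnitude,
        "direction": c.direction,
        "correction": correction_note,
    }


def _groups_by_lifestyle(metrics: pd.DataFrame, metric: str):
    labels = [ls for ls in LIFESTYLE_ORDER if ls in set(metrics["lifestyle"])]
    groups = []
    for ls in labels:
        v = metrics.loc[metrics["lifestyle"] == ls, metric].to_numpy(dtype=float)
        groups.append(v[~np.isnan(v)])
    return groups, labels


def _genome_table(annotation: pd.DataFrame) -> pd.DataFrame:
    cols = ["genome_id", "lifestyle", "genome_size_bp", "trna_count"]
    return annotation[cols].drop_duplicates("genome_id").reset_index(drop=True)


def run_stats(
    config: RunConfig, metrics: pd.DataFrame, annotation: pd.DataFrame
) -> dict:
    """The full statistics bundle (blocks a-g); block failures are isolated."""
    bundle: dict = {
        "seed": config.seed,
        "alpha": 0.05,
        "blocks": {},
    }
    blocks = bundle["blocks"]

    def _run(name: str, enabled: bool, fn):
        if not enabled:
            return
        try:
            blocks[name] = fn()
        except Exception as exc:  # block isolation: log and continue
            logger.exception("stats block %s failed", name)
            blocks[name] = {"error": str(exc)}

    genome_df = _genome_table(annotation)

    # (a) genome size: KW + effect sizes + Dunn
    def _genome_size():
        groups, labels = [], []
        for ls in LIFESTYLE_ORDER:
            sizes = genome_df.loc[
                genome_df["lifestyle"] == ls, "genome_size_bp"
            ].to_numpy(dtype=float)
            if sizes.size:
                groups.append(sizes)
                labels.append(ls)
        kw = pstats.kruskal_wallis(groups)
        kw_uncorr = pstats.kruskal_wallis(groups, tie_correction=False)
        contrasts = pstats.dunn_posthoc(groups, labels)
        return {
            "kruskal_wallis": {
                "H": kw.H, "df": kw.df, "p": kw.p,
                "eta2": kw.eta2, "epsilon2": kw.epsilon2,
                "H_no_tie_correction": kw_uncorr.H,
                "k": kw.k, "N": kw.N,
            },
            "descriptives": {
                ls: describe(
                    genome_df.loc[genome_df["lifestyle"] == ls, "genome_size_bp"]
                    .to_numpy(dtype=float)
                )
                for ls in labels
            },
            "dunn": [_contrast_dict(c, "holm+bonferroni") for c in contrasts],
        }

    _run("genome_size", config.do_genome_size, _genome_size)

    # (b) per-metric omnibus KW with epsilon2 labels
    def _metric_kw():
        out = {}
        for metric in METRICS:
            groups, _ = _groups_by_lifestyle(metrics, metric)
            kw = pstats.kruskal_wallis(groups)
            out[metric] = {
                "H": kw.H, "p": kw.p, "epsilon2": kw.epsilon2,
                "effect": pstats.epsilon2_label(kw.epsilon2), "N": kw.N,
            }
        return out

    _run("metric_kw", config.do_metric_kw, _metric_kw)

    # (c) pairwise Mann-Whitney + Holm + Cliff's delta for significant metrics
    def _pairwise():
        out = {}
        for metric in METRICS:
            groups, labels = _groups_by_lifestyle(metrics, metric)
            kw = pstats.kruskal_wallis(groups)
            if kw.p >= 0.05:
                continue
            contrasts = pstats.pairwise_mannwhitney(groups, labels)
            out[metric] = [_contrast_dict(c, "holm") for c in contrasts]
        return out

    _run("pairwise_contrasts", config.do_pairwise, _pairwise)

    # (d) Spearman + bootstrap CI + BH; partial Spearman controlling GC3 and GC
    def _correlations():
        out = {}
        covariate_names = ("gc3", "gc")
        partial_vars = [m for m in METRICS if m not in covariate_names]
        for ls in LIFESTYLE_ORDER:
            sub = metrics.loc[metrics["lifestyle"] == ls].copy()
            if sub.empty:
                continue
            sub = sub.dropna(subset=["nc"])
            sub["log10_nt"] = np.log10(sub["nt"].astype(float))
            var_names = ["log10_nt"] + [m for m in METRICS if m != "nt"]
            raw_rows, raw_p = [], []
            for i in range(len(var_names)):
                for j in range(i + 1, len(var_names)):
                    x = sub[var_names[i]].to_numpy(dtype=float)
                    y = sub[var_names[j]].to_numpy(dtype=float)
                    r = pstats.spearman(x, y)
                    lo, hi = pstats.bootstrap_ci(
                        x, y, B=config.bootstrap_B, seed=config.seed + 11
                    )
                    raw_rows.append(
                        {
                            "x": var_names[i], "y": var_names[j],
                            "rho": r.rho, "p": r.p,
                            "ci_low": lo, "ci_high": hi, "n": r.n,
                        }
                    )
                    raw_p.append(r.p)
            fdr = pstats.bh_adjust(raw_p)
            for row, q in zip(raw_rows, fdr):
                row["p_fdr"] = float(q)
            part_names = ["log10_nt" if m == "nt" else m for m in partial_vars]
            Z = sub[list(covariate_names)].to_numpy(dtype=float)
            part_rows, part_p = [], []
            for i in range(len(part_names)):
                for j in range(i + 1, len(part_names)):
                    x = sub[part_names[i]].to_numpy(dtype=float)
                    y = sub[part_names[j]].to_numpy(dtype=float)
                    r = pstats.partial_spearman(x, y, Z, covariate_names)
                    part_rows.append(
                        {
                            "x": part_names[i], "y": part_names[j],
                            "rho": r.rho, "p": r.p,
                            "covariates": list(covariate_names), "n": r.n,
                        }
                    )
                    part_p.append(r.p)
            fdr = pstats.bh_adjust(part_p)
            for row, q in zip(part_rows, fdr):
                row["p_fdr"] = float(q)
            out[ls] = {
                "spearman": raw_rows,
                "partial_spearman": part_rows,
                "bootstrap_B": config.bootstrap_B,
                "bootstrap_seed": config.seed + 11,
                "correction": "benjamini-hochberg",
            }
        return out

    _run("correlations", config.do_correlations, _correlations)

    # (e) functional categories: SRH + within-lifestyle + within-category
    def _functional():
        sub = metrics.loc[metrics["category"] != "unclassified"].copy()
        if config.category_unit == "genome_median":
            unit = (
                sub.groupby(["genome_id", "lifestyle", "category"], observed=True)[
                    list(METRICS)
                ]
                .median()
                .reset_index()
            )
        else:
            unit = sub
        out: dict = {"unit": config.category_unit, "srh": {}, "within_lifestyle": {},
                     "within_category": {}}
        for metric in METRICS:
            d = unit.dropna(subset=[metric])
            srh = pstats.scheirer_ray_hare(
                d[metric].to_numpy(dtype=float),
                d["category"].to_numpy(),
                d["lifestyle"].to_numpy(),
            )
            n = len(d)
            out["srh"][metric] = {
                "h_category": srh.h_factor_a, "p_category": srh.p_factor_a,
                "h_lifestyle": srh.h_factor_b, "p_lifestyle": srh.p_factor_b,
                "h_interaction": srh.h_interaction, "p_interaction": srh.p_interaction,
                "epsilon2_category": srh.h_factor_a / (n - 1),
                "epsilon2_lifestyle": srh.h_factor_b / (n - 1),
            }
        for ls in LIFESTYLE_ORDER:
            d_ls = unit.loc[unit["lifestyle"] == ls]
            if d_ls.empty:
                continue
            per_metric = {}
            for metric in METRICS:
                cats = sorted(set(d_ls["category"]))
                groups = [
                    d_ls.loc[d_ls["category"] == c, metric].dropna().to_numpy(dtype=float)
                    for c in cats
                ]
                keep = [(c, g) for c, g in zip(cats, groups) if g.size >= 2]
                if len(keep) < 2:
                    continue
                cats, groups = zip(*keep)
                kw = pstats.kruskal_wallis(groups)
                entry = {"kw_H": kw.H, "kw_p": kw.p, "epsilon2": kw.epsilon2}
                if kw.p < 0.05:
                    entry["dunn"] = [
                        _contrast_dict(c, "holm")
                        for c in pstats.dunn_posthoc(groups, list(cats))
                    ]
                per_metric[metric] = entry
            out["within_lifestyle"][ls] = per_metric
        for category in sorted(set(unit["category"])):
            d_cat = unit.loc[unit["category"] == category]
            per_metric = {}
            for metric in METRICS:
                groups, labels = _groups_by_lifestyle(d_cat, metric)
                groups = [g for g in groups if g.size >= 2]
                if len(groups) < 2:
                    continue
                kw = pstats.kruskal_wallis(groups)
                entry = {"kw_H": kw.H, "kw_p": kw.p, "epsilon2": kw.epsilon2}
                if kw.p < 0.05:
                    entry["contrasts"] = [
                        _contrast_dict(c, "holm")
                        for c in pstats.pairwise_mannwhitney(groups, labels)
                    ]
                per_metric[metric] = entry
            out["within_category"][category] = per_metric
        return out

    _run("functional", config.do_functional, _functional)

    # (f) PERMANOVA + PERMDISP per lifestyle pair
    def _permanova():
        sub = metrics.dropna(subset=["nc"])
        out = {}
        lifestyles = [ls for ls in LIFESTYLE_ORDER if ls in set(sub["lifestyle"])]
        for i in range(len(lifestyles)):
            for j in range(i + 1, len(lifestyles)):
                pair = (lifestyles[i], lifestyles[j])
                d = sub.loc[sub["lifestyle"].isin(pair)]
                X = d[list(METRICS)].to_numpy(dtype=float)
                labels = d["lifestyle"].to_numpy()
                n_min = min(int(np.sum(labels == g)) for g in pair)
                sub_n = config.permanova_subsample_n or n_min
                sub_n = min(sub_n, n_min)
                res = pstats.permanova(
                    X, labels, n_perm=config.n_perm,
                    subsample_n=sub_n, seed=config.seed + 23,
                )
                out[f"{pair[0]}_vs_{pair[1]}"] = {
                    "pseudo_f": res.pseudo_f, "r2": res.r2, "p": res.p,
                    "n_perm": res.n_perm, "subsample_n": res.subsample_n,
                    "seed": res.seed,
                    "permdisp_f": res.dispersion_f, "permdisp_p": res.dispersion_p,
                }
        return out

    _run("permanova", config.do_permanova, _permanova)

    # (g) genome size vs tRNA count (virulent group, genome level)
    def _trna():
        vir = genome_df.loc[genome_df["lifestyle"] == "virulent"].dropna(
            subset=["trna_count"]
        )
        if len(vir) < 4:
            raise ValidationError("too few virulent genomes with tRNA counts")
        r = pstats.spearman(
            vir["genome_size_bp"].to_numpy(dtype=float),
            vir["trna_count"].to_numpy(dtype=float),
        )
        sizes = vir["genome_size_bp"].to_numpy(dtype=float)
        counts = vir["trna_count"].to_numpy(dtype=float)
        return {
            "genome_size_vs_trna_count": {"rho": r.rho, "p": r.p, "n": r.n},
            "trna_only_in_large_genomes": bool(
                np.all(sizes[counts > 0] >= np.max(sizes[counts == 0], initial=0))
            ),
        }

    _run("trna", config.do_trna, _trna)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle


# ---------------------------------------------------------------------------
# run-all


def run_all(config: RunConfig) -> dict:
    """simulate/load → metrics → distances → statistics; returns everything."""
    inputs = load_inputs(config)
    metrics, summaries = run_metrics(config, inputs)
    annotation = pio.annotation_frame(inputs[1])
    pair_tables, het_summaries = run_distance(config, inputs)
    bundle = run_stats(config, metrics, annotation)
    if config.out_dir:
        out = Path(config.out_dir)
        manifest = {
            "seed": config.seed,
            "simulate": config.simulate,
            "inputs": {
                "fasta": str(config.fasta) if config.fasta else None,
                "codon_table": str(config.codon_table) if config.codon_table else None,
                "hits": str(config.hits) if config.hits else None,
                "annotation": str(config.annotation) if config.annotation else None,
            },
            "n_perm": config.n_perm,
            "bootstrap_B": config.bootstrap_B,
            "category_unit": config.category_unit,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "metrics": metrics,
        "summaries": summaries,
        "pairs": pair_tables,
        "heterogeneity": het_summaries,
        "stats": bundle,
        "annotation": annotation,
    }
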