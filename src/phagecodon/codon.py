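"""Per-gene compositional and codon-usage metrics.

Computes, for each CDS: length (nt), overall and position-specific GC content
(%GC, %GC1, %GC2, %GC3), the Codon Adaptation Index (CAI; geometric mean of
relative adaptiveness weights w = f/f_max within each synonymous family,
after Sharp & Li), and Wright's effective number of codons (Nc, from
synonymous-family homozygosities). Also assigns functional gene categories
(structural / regulatory / lysis / replication / repair) from product strings.

Conventions applied uniformly (see docs/methods.md): the terminal stop codon
is excluded from GC, CAI and Nc; codons containing N and internal stop codons
are excluded from all codon-level computations; ATG and TGG (single-codon
families) do not enter CAI's geometric mean; Nc is capped at 61 and reported
as unset (None) when the required family averages are unavailable.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import pandas as pd

from ._genetic_code import (
    FAMILIES_PER_DEGENERACY,
    GENETIC_CODE,
    SINGLE_CODON_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .errors import FrameError, UndefinedMetricError, ValidationError
from .io import CdsRecord, CodonUsageTable

logger = logging.getLogger(__name__)

NC_MAX = 61.0
NC_MIN = 20.0


@dataclass(frozen=True)
class AdaptivenessWeights:
    """Relative adaptiveness w (codon → (0, 1]); stops/single-codon families excluded."""

    w: dict[str, float]
    excluded: frozenset[str]


@dataclass(frozen=True)
class GeneMetrics:
    """The seven per-gene metrics plus bookkeeping counts."""

    nt: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    cai: float
    nc: float | None
    n_codons_used: int
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# codon bookkeeping


def split_codons(sequence: str, trim_terminal_stop: bool = True):
    """Split an in-frame CDS into (kept codons, n_excluded, terminal_stop or None).

    Kept codons are those entering codon-level metrics: N-containing codons and
    internal stop codons are excluded (the excluded count is returned);
    the terminal stop, when present and ``trim_terminal_stop``, is returned
    separately.
    """
    if len(sequence) < 3:
        raise FrameError(f"sequence of length {len(sequence)} has no complete codon")
    if len(sequence) % 3:
        raise FrameError(
            f"sequence length {len(sequence)} is not a multiple of 3 (trailing partial codon)"
        )
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    terminal_stop = None
    if trim_terminal_stop and codons[-1] in STOP_CODONS:
        terminal_stop = codons.pop()
    kept: list[str] = []
    n_excluded = 0
    n_internal_stops = 0
    for c in codons:
        if "N" in c:
            n_excluded += 1
        elif c in STOP_CODONS:
            n_excluded += 1
            n_internal_stops += 1
        else:
            kept.append(c)
    if n_internal_stops:
        logger.warning("sequence contains %d internal stop codon(s)", n_internal_stops)
    return kept, n_excluded, terminal_stop


# ---------------------------------------------------------------------------
# GC content


def positional_gc(
    sequence: str, include_terminal_stop: bool = False
) -> tuple[float, float, float, float]:
    """Overall and position-specific GC percentages of an in-frame CDS.

    gcK = 100 x (G+C at codon position K) / (codons counted); gc is computed
    over all three positions of the counted codons. With no exclusions,
    gc = (gc1 + gc2 + gc3) / 3 exactly.
    """
    kept, _, terminal_stop = split_codons(
        sequence, trim_terminal_stop=not include_terminal_stop
    )
    if include_terminal_stop and terminal_stop is not None:  # pragma: no cover
        kept.append(terminal_stop)
    if not kept:
        raise UndefinedMetricError("all codons excluded; GC undefined")
    n = len(kept)
    gc_pos = [0, 0, 0]
    for c in kept:
        for k in range(3):
            if c[k] in "GC":
                gc_pos[k] += 1
    gc1, gc2, gc3 = (100.0 * g / n for g in gc_pos)
    gc = 100.0 * sum(gc_pos) / (3 * n)
    return gc, gc1, gc2, gc3


# ---------------------------------------------------------------------------
# CAI


def adaptiveness_weights(
    table: CodonUsageTable, zero_rule: float = 0.5
) -> AdaptivenessWeights:
    """Sharp & Li relative adaptiveness from a reference usage table.

    Within each synonymous family w(codon) = count / max family count.
    Reference codons with a zero count receive ``zero_rule`` as a pseudo-count
    before normalisation, so no weight is ever zero. Stop codons and the
    single-codon families (ATG, TGG) are excluded from CAI and carried in
    ``excluded``.
    """
    w: dict[str, float] = {}
    excluded = set(STOP_CODONS)
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if aa in SINGLE_CODON_AA:
            excluded.update(codons)
            continue
        counts = {c: float(table.count(c)) for c in codons}
        if all(v == 0 for v in counts.values()):
            raise ValidationError(
                f"reference table unusable: family {aa} has all-zero counts"
            )
        counts = {c: (v if v > 0 else zero_rule) for c, v in counts.items()}
        fmax = max(counts.values())
        for c, v in counts.items():
            w[c] = v / fmax
    return AdaptivenessWeights(w=w, excluded=frozenset(excluded))


def cai(sequence: str, weights: AdaptivenessWeights) -> float:
    """Codon Adaptation Index: geometric mean of w over the gene's codons.

    Computed in the log domain. Stop codons, single-codon families and
    N-containing codons do not contribute.
    """
    kept, _, _ = split_codons(sequence)
    log_sum = 0.0
    n = 0
    for c in kept:
        if c in weights.excluded:
            continue
        log_sum += math.log(weights.w[c])
        n += 1
    if n == 0:
        raise UndefinedMetricError("no codons contribute to CAI")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# Nc


def _family_counts(kept_codons: list[str]) -> dict[str, dict[str, int]]:
    fam: dict[str, dict[str, int]] = {}
    for c in kept_codons:
        aa = GENETIC_CODE[c]
        fam.setdefault(aa, {})
        fam[aa][c] = fam[aa].get(c, 0) + 1
    return fam


def nc(sequence: str) -> float | None:
    """Wright's effective number of codons (20 = maximal bias, 61 = none).

    Per synonymous family, homozygosity F = (n * sum(p_i^2) - 1) / (n - 1)
    with n the family codon count; families with n < 2 or F <= 0 are dropped.
    Mean F per degeneracy class k gives Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
    A missing three-fold class (Ile) is imputed via
    1/F3 = (1/F2 + 1/F4) / 2; if the two-, four- or six-fold class average is
    unavailable the estimate is undefined and None is returned. Values above
    61 (a small-sample artefact of the estimator) are capped at 61.
    """
    kept, _, _ = split_codons(sequence)
    fam_counts = _family_counts(kept)
    f_by_deg: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, counts in fam_counts.items():
        k = len(SYNONYMOUS_FAMILIES[aa])
        if k == 1:
            continue
        n = sum(counts.values())
        if n < 2:
            continue
        sum_p2 = sum((v / n) ** 2 for v in counts.values())
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        if f_hat > 0:
            f_by_deg[k].append(f_hat)
    f_bar = {k: (sum(v) / len(v) if v else None) for k, v in f_by_deg.items()}
    if f_bar[2] is None or f_bar[4] is None or f_bar[6] is None:
        return None
    if f_bar[3] is not None:
        inv_f3 = 1.0 / f_bar[3]
    else:
        inv_f3 = (1.0 / f_bar[2] + 1.0 / f_bar[4]) / 2.0
    value = (
        2.0
        + FAMILIES_PER_DEGENERACY[2] / f_bar[2]
        + 1.0 * inv_f3
        + FAMILIES_PER_DEGENERACY[4] / f_bar[4]
        + FAMILIES_PER_DEGENERACY[6] / f_bar[6]
    )
    return min(value, NC_MAX)


# ---------------------------------------------------------------------------
# composition


def gene_metrics(
    record: CdsRecord,
    weights: AdaptivenessWeights,
    include_terminal_stop_in_gc: bool = False,
) -> GeneMetrics:
    """Bundle nt, GC, CAI and Nc for one CDS. nt is the raw sequence length."""
    kept, n_excluded, _ = split_codons(record.sequence)
    gc, gc1, gc2, gc3 = positional_gc(
        record.sequence, include_terminal_stop=include_terminal_stop_in_gc
    )
    return GeneMetrics(
        nt=len(record.sequence),
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        cai=cai(record.sequence, weights),
        nc=nc(record.sequence),
        n_codons_used=len(kept),
        n_excluded=n_excluded,
    )


def gene_metrics_table(
    records, weights: AdaptivenessWeights, products: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-gene metrics for a batch of CDS records, one row per gene.

    Genes whose metrics fail (frame errors, all codons excluded) are logged
    and skipped rather than aborting the batch. ``products`` optionally
    overrides the product string used for functional classification.
    """
    rows = []
    n_failed = 0
    for rec in records:
        product = (products or {}).get(rec.gene_id, rec.product or "")
        try:
            m = gene_metrics(rec, weights)
        except (FrameError, UndefinedMetricError) as exc:
            n_failed += 1
            logger.warning("gene %s skipped: %s", rec.gene_id, exc)
            continue
        rows.append(
            {
                "gene_id": rec.gene_id,
                "genome_id": rec.genome_id,
                "lifestyle": rec.lifestyle,
                "category": classify_functional_category(product),
                "nt": m.nt,
                "gc": m.gc,
                "gc1": m.gc1,
                "gc2": m.gc2,
                "gc3": m.gc3,
                "cai": m.cai,
                "nc": m.nc,
            }
        )
    if n_failed:
        logger.info("metrics computed for %d genes; %d failed", len(rows), n_failed)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "genome_id", "lifestyle", "category",
            "nt", "gc", "gc1", "gc2", "gc3", "cai", "nc",
        ],
    )


# ---------------------------------------------------------------------------
# functional categories

#: Default keyword vocabularies for product-string classification. The lists
#: are configurable; they cover the canonical phage annotation vocabulary for
#: each functional module and make no claim of being exhaustive.
CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "lysis": ("endolysin", "holin", "amidase", "lysin", "hemolysin"),
    "replication": (
        "replication initiation", "polymerase", "helicase", "primase", "exonuclease",
    ),
    "repair": (
        "methyltransferase", "methylation", "arda", "lar", "hydroxymethylase", "dndb",
    ),
    "regulatory": (
        "repressor", "antirepressor", "activator", "sigma", "anti-sigma",
        "response regulator", "transcriptional regulator",
    ),
    "structural": (
        "packaging", "terminase", "portal", "capsid", "head", "neck", "tail",
        "baseplate", "adsorption",
    ),
}

#: Precedence on multi-keyword hits (first match wins).
CATEGORY_PRECEDENCE = ("lysis", "replication", "repair", "regulatory", "structural")

_CATEGORY_PATTERNS = {
    cat: re.compile(
        "|".join(r"\b" + re.escape(kw) + r"\b" for kw in kws), re.IGNORECASE
    )
    for cat, kws in CATEGORY_KEYWORDS.items()
}


def classify_functional_category(
    product: str | None, keywords: dict[str, tuple[str, ...]] | None = None
) -> str:
    """Assign a functional category from a product annotation string.

    Case-insensitive whole-word keyword matching; on multi-category hits the
    precedence lysis > replication > repair > regulatory > structural applies
    (e.g. 'tail-associated lysin' is lysis, not structural). No hit or an
    empty product gives 'unclassified'.
    """
    if not product:
        return "unclassified"
    if keywords is None:
        patterns = _CATEGORY_PATTERNS
    else:
        patterns = {
            cat: re.compile(
                "|".join(r"\b" + re.escape(kw) + r"\b" for kw in kws), re.IGNORECASE
            )
            for cat, kws in keywords.items()
        }
    for cat in CATEGORY_PRECEDENCE:
        if cat in patterns and patterns[cat].search(product):
            return cat
    return "unclassified"
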