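"""Combined genomic distance (CGD) over unordered genome pairs.

Directional %ID/%Cov hits are averaged per unordered pair; pairs with no hit
in either direction are "no significant similarity" (NSS) and carry the
metric's theoretical maximum, sqrt(2). For valid pairs
d = sqrt((1 - %ID/100)^2 + (1 - %Cov/100)^2), ranging 0 (identical genomes at
full coverage) to sqrt(2). Two summary scopes are produced: valid pairs only,
and all pairs with NSS fixed at sqrt(2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .io import DirectionalHit

logger = logging.getLogger(__name__)

D_MAX = math.sqrt(2.0)


@dataclass(frozen=True)
class GenomePair:
    """One unordered genome pair (ids ordered lexicographically)."""

    genome_a: str
    genome_b: str
    pid: float | None
    pcov: float | None
    nss: bool
    d: float


@dataclass(frozen=True)
class HeterogeneitySummary:
    scope: str  # 'valid_only' or 'all_pairs'
    n_total: int
    n_valid: int
    n_nss: int
    prop_nss: float
    d_stats: dict[str, float]
    pid_stats: dict[str, float] | None = None
    pcov_stats: dict[str, float] | None = None


def cgd(pid: float | None, pcov: float | None) -> float:
    """Combined genomic distance from averaged %ID and %Cov.

    Both unset (an NSS pair) gives exactly sqrt(2); exactly one unset is a
    contract violation.
    """
    if pid is None and pcov is None:
        return D_MAX
    if pid is None or pcov is None:
        raise ValidationError("pid and pcov must be both set or both unset")
    if not (0.0 <= pid <= 100.0 and 0.0 <= pcov <= 100.0):
        raise ValidationError(f"pid={pid}, pcov={pcov} outside [0, 100]")
    d_id = 1.0 - pid / 100.0
    d_cov = 1.0 - pcov / 100.0
    return math.sqrt(d_id * d_id + d_cov * d_cov)


def pair_from_hits(
    hits: Iterable[DirectionalHit], genomes: Sequence[str]
) -> list[GenomePair]:
    """Build all n(n-1)/2 unordered pairs from directional hits.

    Reciprocal directions are averaged per field; a single direction stands on
    its own; listed pairs with no hit in either direction are flagged NSS.
    Duplicate directional rows are averaged with a logged warning.
    """
    genome_set = set(genomes)
    if len(genome_set) != len(genomes):
        raise ValidationError("duplicate genome ids in genome list")
    by_pair: dict[tuple[str, str], list[tuple[float, float]]] = {}
    dup_directions = 0
    seen_directions: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_id not in genome_set or h.subject_id not in genome_set:
            raise ValidationError(
                f"hit references unknown genome: {h.query_id} -> {h.subject_id}"
            )
        if (h.query_id, h.subject_id) in seen_directions:
            dup_directions += 1
        seen_directions.add((h.query_id, h.subject_id))
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        by_pair.setdefault(key, []).append((h.pid, h.pcov))
    if dup_directions:
        logger.warning(
            "%d duplicate directional rows; their values were averaged", dup_directions
        )
    pairs: list[GenomePair] = []
    for a, b in combinations(sorted(genome_set), 2):
        vals = by_pair.get((a, b))
        if vals:
            pid = float(np.mean([v[0] for v in vals]))
            pcov = float(np.mean([v[1] for v in vals]))
            pairs.append(GenomePair(a, b, pid, pcov, nss=False, d=cgd(pid, pcov)))
        else:
            pairs.append(GenomePair(a, b, None, None, nss=True, d=D_MAX))
    return pairs


def _describe(values: np.ndarray) -> dict[str, float]:
    # type-7 (linear interpolation) quartiles; sample (n-1) SD
    return {
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "max": float(np.max(values)),
    }


def summarize(pairs: Sequence[GenomePair], scope: str) -> HeterogeneitySummary:
    """Heterogeneity summary over a pair collection.

    ``valid_only`` drops NSS pairs and also reports %ID/%Cov statistics;
    ``all_pairs`` keeps them at d = sqrt(2).
    """
    if not pairs:
        raise UndefinedMetricError("empty pair collection")
    if scope not in ("valid_only", "all_pairs"):
        raise ValueError(f"unknown scope {scope!r}")
    n_total = len(pairs)
    valid = [p for p in pairs if not p.nss]
    n_nss = n_total - len(valid)
    if scope == "valid_only":
        if not valid:
            raise UndefinedMetricError("no valid pairs; valid_only summary undefined")
        d = np.array([p.d for p in valid])
        return HeterogeneitySummary(
            scope=scope,
            n_total=n_total,
            n_valid=len(valid),
            n_nss=n_nss,
            prop_nss=n_nss / n_total,
            d_stats=_describe(d),
            pid_stats=_describe(np.array([p.pid for p in valid])),
            pcov_stats=_describe(np.array([p.pcov for p in valid])),
        )
    d = np.array([p.d for p in pairs])
    return HeterogeneitySummary(
        scope=scope,
        n_total=n_total,
        n_valid=len(valid),
        n_nss=n_nss,
        prop_nss=n_nss / n_total,
        d_stats=_describe(d),
    )


def pairs_frame(pairs: Sequence[GenomePair]) -> pd.DataFrame:
    """Pair collection as a tidy table (genome_a, genome_b, pid, pcov, nss, d)."""
    return pd.DataFrame(
        [
            {
                "genome_a": p.genome_a,
                "genome_b": p.genome_b,
                "pid": p.pid,
                "pcov": p.pcov,
                "nss": p.nss,
                "d": p.d,
            }
            for p in pairs
        ],
        columns=["genome_a", "genome_b", "pid", "pcov", "nss", "d"],
    )


def summary_dict(s: HeterogeneitySummary) -> dict:
    out = {
        "scope": s.scope,
        "n_total": s.n_total,
        "n_valid": s.n_valid,
        "n_nss": s.n_nss,
        "prop_nss": s.prop_nss,
        "d": s.d_stats,
    }
    if s.pid_stats is not None:
        out["pid"] = s.pid_stats
    if s.pcov_stats is not None:
        out["pcov"] = s.pcov_stats
    return out
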