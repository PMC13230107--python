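"""Per-gene metric correctness: GC positions, CAI, Wright's Nc, classification.

Independent oracles live inside the tests: a direct-product CAI, and an Nc
computed symbol-by-symbol from family counts.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagecodon import codon as cm
from phagecodon._genetic_code import (
    GENETIC_CODE,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)
from phagecodon.errors import FrameError, UndefinedMetricError, ValidationError
from phagecodon.io import CdsRecord, CodonUsageTable

SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def _table_from(counts_override=None, base=100):
    counts = {c: base for c in GENETIC_CODE}
    if counts_override:
        counts.update(counts_override)
    return CodonUsageTable.from_counts(counts)


def _random_cds(rng, n_codons):
    body = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    return body + "TAA"


# ---------------------------------------------------------------------------
# positional GC


def test_positional_gc_hand_counts():
    # ATG AAA: position 1 = A,A; position 2 = T,A; position 3 = G,A
    gc, gc1, gc2, gc3 = cm.positional_gc("ATGAAA")
    assert gc1 == 0 and gc2 == 0 and gc3 == 50
    assert gc == pytest.approx(100 / 6)
    # GCG GCG: every position is G or C
    gc, gc1, gc2, gc3 = cm.positional_gc("GCGGCG")
    assert (gc, gc1, gc2, gc3) == (100, 100, 100, 100)


def test_positional_gc_excludes_terminal_stop():
    # TAA would otherwise dilute GC: ATG alone has GC = 1/3
    gc, *_ = cm.positional_gc("ATGGCGTAA")
    gc_nostop, *_ = cm.positional_gc("ATGGCG")
    assert gc == gc_nostop


def test_positional_gc_frame_errors():
    with pytest.raises(FrameError):
        cm.positional_gc("ATGAAAA")
    with pytest.raises(FrameError):
        cm.positional_gc("AT")


def test_positional_gc_all_excluded():
    with pytest.raises(UndefinedMetricError):
        cm.positional_gc("NNNTAA")


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=1, max_value=400), st.integers())
def test_gc_is_mean_of_positions_without_exclusions(n_codons, seed):
    rng = np.random.default_rng(abs(seed) % 2**31)
    seq = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    gc, gc1, gc2, gc3 = cm.positional_gc(seq)
    assert gc == pytest.approx((gc1 + gc2 + gc3) / 3, abs=1e-9)


# ---------------------------------------------------------------------------
# adaptiveness weights and CAI


def test_weights_direct_ratio():
    t = _table_from({"AAA": 800, "AAG": 200})
    w = cm.adaptiveness_weights(t)
    assert w.w["AAA"] == 1.0
    assert w.w["AAG"] == pytest.approx(0.25)


def test_weights_uniform_table_all_one():
    w = cm.adaptiveness_weights(_table_from())
    assert all(v == 1.0 for v in w.w.values())


def test_weights_zero_count_pseudocount():
    t = _table_from({"GGG": 0})
    w = cm.adaptiveness_weights(t, zero_rule=0.5)
    assert w.w["GGG"] == pytest.approx(0.005)


def test_weights_all_zero_family_rejected():
    with pytest.raises(ValidationError, match="all-zero"):
        cm.adaptiveness_weights(_table_from({"GGG": 0, "GGA": 0, "GGT": 0, "GGC": 0}))


def test_weights_exclude_stops_and_single_codon_families():
    w = cm.adaptiveness_weights(_table_from())
    assert {"ATG", "TGG"} <= set(w.excluded)
    assert STOP_CODONS <= set(w.excluded)
    assert all(c not in w.w for c in w.excluded)


def test_cai_all_preferred_is_one(weights):
    preferred = {
        max(fam, key=lambda c: weights.w.get(c, 0)): aa
        for aa, fam in SYNONYMOUS_FAMILIES.items()
        if aa not in ("M", "W")
    }
    seq = "".join(list(preferred)[:30]) + "TAA"
    assert cm.cai(seq, weights) == pytest.approx(1.0)


def test_cai_two_codon_geometric_mean():
    w = cm.adaptiveness_weights(_table_from({"AAA": 800, "AAG": 200}))
    assert cm.cai("AAAAAG", w) == pytest.approx(0.5)  # sqrt(1 * 0.25)


def test_cai_no_contributing_codons(weights):
    with pytest.raises(UndefinedMetricError):
        cm.cai("ATGTGGTAA", weights)  # Met + Trp only


def test_cai_matches_direct_product_oracle(weights, rng):
    seq = _random_cds(rng, 300)
    kept, _, _ = cm.split_codons(seq)
    contributing = [c for c in kept if c not in weights.excluded]
    product = 1.0
    for c in contributing:
        product *= weights.w[c] ** (1.0 / len(contributing))
    assert cm.cai(seq, weights) == pytest.approx(product, abs=1e-12)


# ---------------------------------------------------------------------------
# Nc


def _nc_oracle(seq):
    """Wright's estimator applied symbol-by-symbol from family counts."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    fams = {}
    for c in codons:
        if c in STOP_CODONS or "N" in c:
            continue
        fams.setdefault(GENETIC_CODE[c], {}).setdefault(c, 0)
        fams[GENETIC_CODE[c]][c] += 1
    per_deg = {2: [], 3: [], 4: [], 6: []}
    for aa, counts in fams.items():
        k = len(SYNONYMOUS_FAMILIES[aa])
        n = sum(counts.values())
        if k == 1 or n < 2:
            continue
        f = (n * sum((v / n) ** 2 for v in counts.values()) - 1) / (n - 1)
        if f > 0:
            per_deg[k].append(f)
    fbar = {k: sum(v) / len(v) if v else None for k, v in per_deg.items()}
    if fbar[2] is None or fbar[4] is None or fbar[6] is None:
        return None
    inv3 = 1 / fbar[3] if fbar[3] is not None else (1 / fbar[2] + 1 / fbar[4]) / 2
    return min(2 + 9 / fbar[2] + inv3 + 5 / fbar[4] + 3 / fbar[6], 61.0)


def test_nc_minimum_20_for_one_codon_per_family():
    seq = ""
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        seq += fam[0] * 2  # one codon type used repeatedly per family
    assert cm.nc(seq) == pytest.approx(20.0)


def test_nc_limit_61_under_uniform_usage():
    seq = "".join(c * 40 for c in SENSE_CODONS)
    value = cm.nc(seq)
    assert value == pytest.approx(61.0, abs=0.1)


def test_nc_capped_at_61():
    # near-uniform tiny families give F-bars far below their asymptotes
    # (e.g. F2 = 1/3 contributes 27 alone), overshooting Wright's maximum;
    # the estimate is capped at 61
    seq = (
        "AAA" * 2 + "AAG"                                    # Lys, F2 = 1/3
        + "ATT" * 2 + "ATC" + "ATA"                          # Ile, F3 = 1/6
        + "GCT" * 2 + "GCA" + "GCC" + "GCG"                  # Ala, F4 = 1/10
        + "TTA" * 2 + "TTG" + "CTT" + "CTC" + "CTA" + "CTG"  # Leu, F6 = 1/21
    )
    assert cm.nc(seq) == pytest.approx(61.0)


def test_nc_unset_when_family_classes_missing():
    assert cm.nc("AAAAAGAAA") is None  # only a single two-fold family


@pytest.mark.parametrize("n_codons", [100, 500])
def test_nc_matches_independent_oracle(rng, n_codons):
    for _ in range(5):
        seq = _random_cds(rng, n_codons)
        expected = _nc_oracle(seq)
        got = cm.nc(seq)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-9)


def test_nc_invariant_under_synonymous_reshuffle(rng):
    # permuting codon order preserves family counts, hence Nc and CAI inputs
    seq = _random_cds(rng, 200)
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    rng.shuffle(codons)
    shuffled = "".join(codons) + "TAA"
    assert cm.nc(seq) == pytest.approx(cm.nc(shuffled), abs=1e-12)


# ---------------------------------------------------------------------------
# gene_metrics bundling


def test_gene_metrics_extremes(weights):
    preferred = [
        max(fam, key=lambda c: weights.w.get(c, 0))
        for aa, fam in SYNONYMOUS_FAMILIES.items()
        if aa not in ("M", "W")
    ]
    seq = "".join(preferred * 3) + "TAA"
    rec = CdsRecord(gene_id="g", genome_id="G", sequence=seq)
    m = cm.gene_metrics(rec, weights)
    assert m.cai == pytest.approx(1.0)
    assert m.nc == pytest.approx(20.0)
    assert m.nt == len(seq)


def test_gene_metrics_batch_skips_broken_gene(weights, rng):
    records = [
        CdsRecord(gene_id=f"g{i}", genome_id="G", sequence=_random_cds(rng, 60))
        for i in range(99)
    ]
    records.append(CdsRecord(gene_id="broken", genome_id="G", sequence="ATGA"))
    table = cm.gene_metrics_table(records, weights)
    assert len(table) == 99
    assert "broken" not in set(table["gene_id"])


def test_gene_metrics_deterministic(weights, rng):
    seq = _random_cds(rng, 80)
    a = cm.gene_metrics(CdsRecord("g", "G", seq), weights)
    b = cm.gene_metrics(CdsRecord("g2", "G", seq), weights)
    assert (a.gc, a.cai, a.nc) == (b.gc, b.cai, b.nc)


# ---------------------------------------------------------------------------
# functional classification


@pytest.mark.parametrize(
    "product,expected",
    [
        ("portal protein", "structural"),
        ("", "unclassified"),
        (None, "unclassified"),
        ("tail-associated lysin", "lysis"),  # lysis outranks structural
        ("DNA polymerase", "replication"),
        ("replication initiation protein", "replication"),
        ("DNA methyltransferase", "repair"),
        ("ArdA antirestriction protein", "repair"),
        ("CI-like repressor", "regulatory"),
        ("anti-sigma factor", "regulatory"),
        ("terminase large subunit", "structural"),  # 'lar' must not hit inside 'large'
        ("hypothetical protein", "unclassified"),
        ("Lar restriction alleviation protein", "repair"),
        ("holin", "lysis"),
    ],
)
def test_classify_functional_category(product, expected):
    assert cm.classify_functional_category(product) == expected


def test_classify_custom_keywords():
    kw = {"lysis": ("spanin",)}
    assert cm.classify_functional_category("i-spanin", keywords=kw) == "lysis"
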