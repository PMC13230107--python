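"""Synthetic lifestyle-structured phage datasets.

Generates everything the pipeline consumes without any download: genome sizes
per lifestyle (truncated-normal mixtures — narrow ~43 kb temperate, broader
~60 kb prophage, bimodal ~17.5 kb / ~135 kb virulent), CDS sequences with
controlled third-position GC and host codon adaptation, functional-category
product strings, per-genome tRNA counts gated on genome size, and pairwise
similarity tables with a tunable fraction of no-significant-similarity (NSS)
pairs.

Codon sampling model: amino acids follow the reference table's amino-acid
frequencies; within each synonymous family a codon is drawn from the host
reference frequencies with probability ``host_mix_alpha``, and otherwise from
a GC3-tilted synonymous distribution (codons ending G/C weighted
gc3_target/100 against its complement). Raising alpha therefore pushes genes
toward host-preferred codons (higher CAI, lower Nc) while the tilt controls
GC3 independently of amino-acid composition, so lifestyle signal is confined
to third codon positions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._genetic_code import STOP_CODONS, SYNONYMOUS_FAMILIES
from .errors import ValidationError
from .io import AnnotationRow, CdsRecord, CodonUsageTable, DirectionalHit

logger = logging.getLogger(__name__)

CATEGORIES = ("structural", "regulatory", "lysis", "replication", "repair", "unclassified")

#: Product strings the generator draws from, keyed by the functional category
#: the classifier should recover.
CATEGORY_PRODUCTS: dict[str, tuple[str, ...]] = {
    "structural": (
        "portal protein", "major capsid protein", "terminase large subunit",
        "tail fiber protein", "baseplate wedge protein",
        "head morphogenesis protein", "neck passage structure protein",
    ),
    "regulatory": (
        "transcriptional regulator", "CI-like repressor", "antirepressor",
        "sigma factor", "two-component response regulator",
    ),
    "lysis": (
        "endolysin", "holin", "N-acetylmuramoyl-L-alanine amidase",
        "hemolysin-family protein",
    ),
    "replication": (
        "DNA polymerase", "replicative helicase", "DNA primase",
        "replication initiation protein", "5'-3' exonuclease",
    ),
    "repair": (
        "DNA methyltransferase", "ArdA antirestriction protein",
        "dCMP hydroxymethylase", "DndB DNA sulfur modification protein",
    ),
    "unclassified": ("hypothetical protein", "phage protein", "membrane protein"),
}


# ---------------------------------------------------------------------------
# synthetic host reference table

#: Amino-acid composition of an AT-rich staphylococcal-style proteome
#: (fractions; normalised in code).
_AA_FREQS = {
    "K": 0.076, "I": 0.075, "E": 0.071, "L": 0.095, "N": 0.052, "D": 0.057,
    "S": 0.060, "A": 0.064, "V": 0.068, "G": 0.068, "T": 0.054, "F": 0.045,
    "Q": 0.038, "R": 0.045, "Y": 0.035, "P": 0.037, "H": 0.022, "M": 0.025,
    "W": 0.010, "C": 0.008,
}

#: Within-family preference by third base for the synthetic host (AT-rich,
#: A-ending codons preferred), renormalised over the codons a family has.
_HOST_THIRD_BASE_WEIGHT = {"A": 0.55, "T": 0.30, "G": 0.09, "C": 0.06}


def synthetic_host_table(total_codons: int = 1_500_000) -> CodonUsageTable:
    """Synthetic host reference codon-usage table (a constructed stand-in).

    Emulates the usage of an AT-rich, low-GC gram-positive host: amino-acid
    frequencies of a staphylococcal-style proteome and a strong within-family
    preference for A/T-ending codons. Deterministic; not derived from any
    downloaded table.
    """
    aa_total = sum(_AA_FREQS.values())
    counts: dict[str, int] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        aa_count = total_codons * _AA_FREQS[aa] / aa_total
        weights = np.array([_HOST_THIRD_BASE_WEIGHT[c[2]] for c in codons])
        weights = weights / weights.sum()
        for c, w in zip(codons, weights):
            counts[c] = max(1, round(aa_count * w))
    # stop codons: one per CDS on average; AT-rich hosts favour TAA
    n_stops = max(1, total_codons // 330)
    for c, w in (("TAA", 0.8), ("TAG", 0.12), ("TGA", 0.08)):
        counts[c] = max(1, round(n_stops * w))
    return CodonUsageTable.from_counts(counts)


# ---------------------------------------------------------------------------
# profiles and config


@dataclass(frozen=True)
class LifestyleProfile:
    """Generator parameters for one lifestyle group.

    ``genome_size_model`` is a tuple of truncated-normal components
    (weight, mean_bp, sd_bp, low_bp, high_bp); ``gene_length_model`` is
    (mu, sigma) of a log-normal on codon counts with ``min_codons`` floor;
    ``host_mix_alpha`` is the probability a codon follows host usage rather
    than the GC3 tilt; ``trna_model`` is (min_genome_bp, presence_prob,
    count_low, count_high).
    """

    lifestyle: str
    genome_size_model: tuple[tuple[float, float, float, float, float], ...]
    gc3_target: float
    host_mix_alpha: float
    nss_rate: float
    pid_mean: float
    pid_sd: float = 6.0
    gene_length_model: tuple[float, float] = (np.log(130.0), 0.9)
    min_codons: int = 21
    cds_fill_fraction: float = 0.9
    trna_model: tuple[float, float, int, int] = (0.0, 0.0, 0, 0)

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.genome_size_model)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"{self.lifestyle}: mixture weights sum to {w}, not 1")
        if not 0.0 <= self.host_mix_alpha <= 1.0:
            raise ValidationError(f"{self.lifestyle}: host_mix_alpha outside [0, 1]")
        if not 0.0 <= self.nss_rate <= 1.0:
            raise ValidationError(f"{self.lifestyle}: nss_rate outside [0, 1]")


#: Default lifestyle profiles. Genome-size mixtures and GC3 tilt targets follow
#: the observed per-lifestyle regimes (temperate 43.3 +/- 1.4 kb; prophage
#: right-skewed around ~60 kb; virulent bimodal ~17.5 kb / ~135 kb; GC3 medians
#: 19.8 / 28.0 / 25.8); NSS rates 0.591 / 0 / 0.055 and %ID means per group.
#: host_mix_alpha values are calibrated so generated CAI/Nc group means sit in
#: the observed ranges (virulent ~0.72/37, temperate ~0.65/44).
DEFAULT_PROFILES: dict[str, LifestyleProfile] = {
    "virulent": LifestyleProfile(
        lifestyle="virulent",
        genome_size_model=(
            (0.42, 17_500.0, 600.0, 16_784.0, 19_500.0),
            (0.58, 135_000.0, 7_000.0, 120_000.0, 148_511.0),
        ),
        gc3_target=19.8,
        host_mix_alpha=0.85,
        nss_rate=0.591,
        pid_mean=86.89,
        trna_model=(120_000.0, 0.56, 2, 15),
    ),
    "temperate": LifestyleProfile(
        lifestyle="temperate",
        genome_size_model=((1.0, 43_297.0, 1_423.0, 39_968.0, 45_985.0),),
        gc3_target=28.0,
        host_mix_alpha=0.25,
        nss_rate=0.0,
        pid_mean=83.51,
    ),
    "prophage": LifestyleProfile(
        lifestyle="prophage",
        genome_size_model=((1.0, 57_000.0, 12_000.0, 43_363.0, 130_595.0),),
        gc3_target=25.8,
        host_mix_alpha=0.40,
        nss_rate=0.055,
        pid_mean=84.62,
    ),
}

DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "structural": 0.35,
    "regulatory": 0.12,
    "lysis": 0.06,
    "replication": 0.15,
    "repair": 0.05,
    "unclassified": 0.27,
}


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; the seed is mandatory."""

    seed: int
    n_genomes: int = 30
    profiles: dict[str, LifestyleProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_genomes <= 0:
            raise ValidationError("n_genomes must be positive")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"category_mix sums to {total}, not 1")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown categories: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# sampling


def sample_genome_sizes(
    profile: LifestyleProfile, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n genome sizes (bp) from the profile's truncated-normal mixture."""
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    weights = np.array([c[0] for c in profile.genome_size_model])
    comp = rng.choice(len(weights), size=n, p=weights)
    sizes = np.empty(n)
    for i, (w, mean, sd, low, high) in enumerate(profile.genome_size_model):
        m = comp == i
        if m.any():
            a, b = (low - mean) / sd, (high - mean) / sd
            sizes[m] = sps.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=int(m.sum()), random_state=rng
            )
    return np.round(sizes).astype(int)


def _codon_sampler(
    gc3_target: float, host_mix_alpha: float, table: CodonUsageTable
) -> tuple[np.ndarray, np.ndarray]:
    """Joint codon distribution implied by the two-step draw.

    Amino acid ~ reference amino-acid frequencies; codon | aa is the
    alpha-mixture of host within-family usage and the GC3 tilt. The joint over
    the 61 sense codons is their product, which is what is sampled.
    """
    t = gc3_target / 100.0
    if not 0.0 < t < 1.0:
        clamped = min(max(t, 0.01), 0.99)
        logger.warning("gc3_target %.1f%% clamped to %.0f%%", gc3_target, clamped * 100)
        t = clamped
    codons: list[str] = []
    probs: list[float] = []
    aa_counts = {
        aa: sum(table.count(c) for c in fam)
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    total_sense = sum(aa_counts.values())
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        host = np.array([table.count(c) for c in fam], dtype=float)
        host = host / host.sum() if host.sum() > 0 else np.full(len(fam), 1 / len(fam))
        tilt = np.array([t if c[2] in "GC" else 1.0 - t for c in fam])
        tilt = tilt / tilt.sum()
        mix = host_mix_alpha * host + (1.0 - host_mix_alpha) * tilt
        p_aa = aa_counts[aa] / total_sense
        codons.extend(fam)
        probs.extend(p_aa * mix)
    return np.array(codons), np.array(probs) / np.sum(probs)


def generate_cds(
    n_codons: int,
    gc3_target: float,
    host_mix_alpha: float,
    table: CodonUsageTable,
    seed: int | np.random.Generator,
) -> str:
    """One synthetic CDS of exactly 3*n_codons nt: ATG, interior, single stop."""
    if n_codons < 21:
        raise ValidationError("n_codons must be >= 21")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codons, probs = _codon_sampler(gc3_target, host_mix_alpha, table)
    interior = rng.choice(codons, size=n_codons - 2, p=probs)
    stops = sorted(STOP_CODONS)
    stop_counts = np.array([table.count(c) for c in stops], dtype=float)
    stop_p = stop_counts / stop_counts.sum() if stop_counts.sum() else None
    stop = rng.choice(stops, p=stop_p)
    return "ATG" + "".join(interior) + stop


def _gene_codon_counts(
    profile: LifestyleProfile, target_nt: float, rng: np.random.Generator
) -> list[int]:
    """Gene lengths (codons) filling ~target_nt of CDS sequence."""
    mu, sigma = profile.gene_length_model
    lengths: list[int] = []
    total = 0.0
    while total < target_nt:
        n = max(profile.min_codons, int(round(rng.lognormal(mu, sigma))))
        lengths.append(n)
        total += 3 * n
    return lengths


def generate_dataset(
    config: SimConfig, table: CodonUsageTable | None = None
) -> tuple[list[CdsRecord], list[AnnotationRow]]:
    """Generate genomes, CDSs, annotations and tRNA counts for all lifestyles.

    All randomness flows from one generator seeded with ``config.seed``;
    summed CDS length per genome is ~``cds_fill_fraction`` of genome size.
    """
    if table is None:
        table = synthetic_host_table()
    rng = np.random.default_rng([config.seed, 1])
    cats = list(config.category_mix)
    cat_p = np.array([config.category_mix[c] for c in cats])
    records: list[CdsRecord] = []
    rows: list[AnnotationRow] = []
    for lifestyle in sorted(config.profiles):
        profile = config.profiles[lifestyle]
        sampler_codons, sampler_probs = _codon_sampler(
            profile.gc3_target, profile.host_mix_alpha, table
        )
        stops = sorted(STOP_CODONS)
        stop_counts = np.array([table.count(c) for c in stops], dtype=float)
        stop_p = stop_counts / stop_counts.sum()
        sizes = sample_genome_sizes(profile, config.n_genomes, rng)
        for gi, size in enumerate(sizes, start=1):
            genome_id = f"{lifestyle}_{gi:02d}"
            gate, prob, lo, hi = profile.trna_model
            trna = 0
            if size >= gate and prob > 0 and rng.random() < prob:
                trna = int(rng.integers(lo, hi + 1))
            gene_lengths = _gene_codon_counts(
                profile, profile.cds_fill_fraction * size, rng
            )
            for gj, n_codons in enumerate(gene_lengths, start=1):
                interior = rng.choice(sampler_codons, size=n_codons - 2, p=sampler_probs)
                stop = rng.choice(stops, p=stop_p)
                seq = "ATG" + "".join(interior) + stop
                category = cats[rng.choice(len(cats), p=cat_p)]
                product = str(rng.choice(CATEGORY_PRODUCTS[category]))
                gene_id = f"{genome_id}_g{gj:04d}"
                records.append(
                    CdsRecord(
                        gene_id=gene_id,
                        genome_id=genome_id,
                        sequence=seq,
                        lifestyle=lifestyle,
                        product=product,
                    )
                )
                rows.append(
                    AnnotationRow(
                        gene_id=gene_id,
                        genome_id=genome_id,
                        lifestyle=lifestyle,
                        product=product,
                        trna_count=trna,
                        genome_size_bp=int(size),
                    )
                )
    return records, rows


def genome_ids(config: SimConfig, lifestyle: str) -> list[str]:
    """Deterministic genome ids for one lifestyle group of a config."""
    return [f"{lifestyle}_{i:02d}" for i in range(1, config.n_genomes + 1)]


def generate_similarity_table(config: SimConfig) -> list[DirectionalHit]:
    """Within-group all-versus-all similarity hits with a tunable NSS fraction.

    For each within-group unordered pair: with probability ``nss_rate`` no hit
    is emitted in either direction; otherwise both directions are emitted with
    %ID around the group mean (truncated normal, [50, 100]) and broad, mostly
    partial query coverage.
    """
    rng = np.random.default_rng([config.seed, 2])
    hits: list[DirectionalHit] = []
    for lifestyle in sorted(config.profiles):
        profile = config.profiles[lifestyle]
        ids = genome_ids(config, lifestyle)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < profile.nss_rate:
                    continue
                a, b = (profile.pid_mean, profile.pid_sd)
                lo, hi = (50.0 - a) / b, (100.0 - a) / b
                base_pid = float(
                    sps.truncnorm.rvs(lo, hi, loc=a, scale=b, random_state=rng)
                )
                base_cov = float(100.0 * rng.beta(0.8, 2.6))
                for q, s in ((ids[i], ids[j]), (ids[j], ids[i])):
                    pid = float(np.clip(base_pid + rng.normal(0, 1.0), 50.0, 100.0))
                    pcov = float(np.clip(base_cov + rng.normal(0, 2.0), 0.5, 100.0))
                    hits.append(DirectionalHit(q, s, pid, pcov))
    return hits
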