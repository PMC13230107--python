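"""Standard (bacterial) genetic code: codon→amino-acid map and synonymous families.

Degeneracy structure used by Wright's Nc: 9 two-fold, 1 three-fold (Ile),
5 four-fold and 3 six-fold families; Met and Trp are single-codon families and
carry no synonymous information; the 3 stop codons are excluded throughout.
"""

from __future__ import annotations

BASES = "TCAG"

# Standard genetic code (NCBI table 1 / 11 share this codon→aa map).
GENETIC_CODE: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_i = 0
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA_ORDER[_i]
            _i += 1

CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
STOP_CODONS: frozenset[str] = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
START_CODON = "ATG"

# Synonymous families keyed by amino acid (stops excluded).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa == "*":
        continue
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES = {a: tuple(sorted(cs)) for a, cs in SYNONYMOUS_FAMILIES.items()}

# Amino acids grouped by family degeneracy (Met/Trp are degeneracy 1).
DEGENERACY: dict[str, int] = {a: len(cs) for a, cs in SYNONYMOUS_FAMILIES.items()}
SINGLE_CODON_AA: frozenset[str] = frozenset(a for a, k in DEGENERACY.items() if k == 1)

# Wright's class sizes: number of families at each degeneracy level.
FAMILIES_PER_DEGENERACY: dict[int, int] = {}
for _aa, _k in DEGENERACY.items():
    if _k > 1:
        FAMILIES_PER_DEGENERACY[_k] = FAMILIES_PER_DEGENERACY.get(_k, 0) + 1
assert FAMILIES_PER_DEGENERACY == {2: 9, 3: 1, 4: 5, 6: 3}
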