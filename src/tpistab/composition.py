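"""Sequence/composition-derived physical parameters.

Given an amino acid composition this module computes the three quantities a
sedimentation-equilibrium analysis needs before any centrifuge data are
touched: the monomer molecular weight, the 280-nm molar extinction
coefficient, and the temperature-corrected partial specific volume (vbar).
All three are simple sums over embedded residue tables, which makes them
exactly reproducible and easy to audit.

Expression constructs frequently carry a purification tag that is part of
the sedimenting species but not of the ORF; :class:`ResidueCounts` therefore
keeps an optional tag composition separate so the ORF-only and whole-construct
views are both available.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from Bio import SeqIO

from ._tables import (
    EXTINCTION_280,
    RESIDUE_MASS_DA,
    RESIDUE_VBAR_25C,
    STANDARD_AA,
    VBAR_TEMP_SLOPE,
    WATER_MASS_DA,
)

__all__ = [
    "ResidueCounts",
    "molecular_weight",
    "molar_extinction_280",
    "partial_specific_volume",
    "read_fasta_counts",
]


def _validate_counts(counts: Mapping[str, int], what: str) -> dict[str, int]:
    clean: dict[str, int] = {}
    for aa, n in counts.items():
        code = aa.upper()
        if code not in STANDARD_AA:
            raise ValueError(f"unknown residue code {aa!r} in {what}")
        if int(n) != n or n < 0:
            raise ValueError(f"count for {code} must be a non-negative integer, got {n!r}")
        if n:
            clean[code] = clean.get(code, 0) + int(n)
    return clean


@dataclass(frozen=True)
class ResidueCounts:
    """Amino acid composition, optionally with a separate appended-tag part.

    Parameters
    ----------
    counts
        Residue counts of the main chain (one-letter codes, 20 standard
        amino acids only).
    tag_counts
        Residue counts of an appended tag (e.g. a C-terminal His6 plus
        linker).  Kept separate so that ORF-level metrics such as the
        proline fraction can ignore it while mass/extinction/vbar include it.
    """

    counts: Mapping[str, int]
    tag_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", _validate_counts(self.counts, "counts"))
        object.__setattr__(self, "tag_counts", _validate_counts(self.tag_counts, "tag_counts"))

    @classmethod
    def from_sequence(cls, sequence: str, tag: str = "") -> "ResidueCounts":
        return cls(Counter(sequence.upper()), Counter(tag.upper()))

    @property
    def length(self) -> int:
        """Total residue count, tag included."""
        return sum(self.counts.values()) + sum(self.tag_counts.values())

    def count(self, aa: str) -> int:
        code = aa.upper()
        return self.counts.get(code, 0) + self.tag_counts.get(code, 0)

    def items(self) -> Iterator[tuple[str, int]]:
        merged = Counter(self.counts)
        merged.update(self.tag_counts)
        for aa in STANDARD_AA:
            if merged.get(aa):
                yield aa, merged[aa]

    def __add__(self, other: "ResidueCounts") -> "ResidueCounts":
        a, b = Counter(self.counts), Counter(other.counts)
        ta, tb = Counter(self.tag_counts), Counter(other.tag_counts)
        return ResidueCounts(a + b, ta + tb)


def molecular_weight(counts: ResidueCounts) -> float:
    """Average-isotopic molecular weight in Da (residue masses + one water).

    An empty composition is degenerate and returns the mass of water alone,
    with a warning.
    """
    if counts.length == 0:
        warnings.warn("empty composition: molecular weight is that of water alone",
                      stacklevel=2)
        return WATER_MASS_DA
    return sum(n * RESIDUE_MASS_DA[aa] for aa, n in counts.items()) + WATER_MASS_DA


def molar_extinction_280(counts: ResidueCounts, cystine_pairs: int = 0,
                         convention: str = "pace") -> float:
    """Molar extinction coefficient at 280 nm in M^-1 cm^-1.

    eps = nTrp * eW + nTyr * eY + cystine_pairs * eSS with the chosen
    coefficient convention (``"pace"`` default, ``"gill-von-hippel"``
    alternative).  ``cystine_pairs`` counts disulfide bridges; the default 0
    is the fully reduced assumption.
    """
    if cystine_pairs < 0:
        raise ValueError("cystine_pairs must be >= 0")
    if cystine_pairs > counts.count("C") // 2:
        raise ValueError(
            f"cystine_pairs={cystine_pairs} exceeds floor(nCys/2)={counts.count('C') // 2}"
        )
    try:
        coef = EXTINCTION_280[convention]
    except KeyError:
        raise ValueError(f"unknown extinction convention {convention!r}") from None
    return (counts.count("W") * coef["W"] + counts.count("Y") * coef["Y"]
            + cystine_pairs * coef["cystine"])


def partial_specific_volume(counts: ResidueCounts, temperature_K: float = 293.15) -> float:
    """Partial specific volume (cm^3/g) at ``temperature_K``.

    Mass-weighted Cohn-Edsall average of per-residue vbar values at 25 degC,

        vbar(25) = sum(n_i m_i vbar_i) / sum(n_i m_i),

    then corrected with the standard linear rule
    vbar(T) = vbar(25 degC) + 4.25e-4 * (T - 298.15).
    """
    if not 273.15 <= temperature_K <= 373.15:
        raise ValueError("temperature must lie within 273.15-373.15 K")
    if counts.length == 0:
        raise ValueError("cannot compute vbar of an empty composition")
    mass = sum(n * RESIDUE_MASS_DA[aa] for aa, n in counts.items())
    vol = sum(n * RESIDUE_MASS_DA[aa] * RESIDUE_VBAR_25C[aa] for aa, n in counts.items())
    return vol / mass + VBAR_TEMP_SLOPE * (temperature_K - 298.15)


def read_fasta_counts(path, tag: str = "") -> ResidueCounts:
    """Composition of the first record in a FASTA file (optional appended tag)."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA records in {path}")
    return ResidueCounts.from_sequence(str(record.seq), tag=tag)
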