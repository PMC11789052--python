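"""Detection of RGG motifs in protein sequences.

An RGG motif is at least two consecutive RG or RGG repeat units, interspersed
by linkers of at most 4 arbitrary amino acids::

    RG{1,2} ( X{0,4} RG{1,2} )+        X = any amino acid

Matches are maximal, mutually non-overlapping, and resolved leftmost-longest:
a reported motif cannot be extended by another repeat unit within linker
distance on either side.  Repeat units never overlap, a motif always starts
at the R of its first unit and ends at the final G of its last unit (trailing
would-be linker residues are not part of the span), and motifs never span the
unknown residue ``X`` or a stop symbol ``*``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "RGGMotif",
    "find_rgg_motifs",
    "motif_features",
    "motif_cds_interval",
    "min_motif_length",
]

# linker residues: any uppercase amino-acid letter except the unknown 'X'
_LINKER_CLASS = "ABCDEFGHIJKLMNOPQRSTUVWYZ"

# Lazy linker + greedy unit repetition implements the maximal-extent
# convention: at every step the nearest next unit is absorbed (which never
# shortens the reachable extent, since any skipped unit would itself be
# reachable from the absorbed one), and extension is always preferred over
# terminating the match.
_MOTIF_RE = re.compile(rf"RG{{1,2}}(?:[{_LINKER_CLASS}]{{0,4}}?RG{{1,2}})+")


@dataclass(frozen=True)
class RGGMotif:
    """A maximal RGG-grammar match.

    Coordinates are 0-based half-open amino-acid indices into the protein.
    ``units`` holds ``(start, "RG"|"RGG")`` pairs; ``linkers`` the inter-unit
    stretches (each 0-4 residues).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    units: tuple[tuple[int, str], ...]
    linkers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.units) < 2:
            raise ValueError("an RGG motif has at least two repeat units")
        if len(self.linkers) != len(self.units) - 1:
            raise ValueError("expected one linker between consecutive units")
        if any(len(lk) > 4 for lk in self.linkers):
            raise ValueError("linker longer than 4 residues")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence/coordinate mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_rg(self) -> int:
        return sum(1 for _, u in self.units if u == "RG")

    @property
    def n_rgg(self) -> int:
        return sum(1 for _, u in self.units if u == "RGG")


def _decompose(seq: str, offset: int) -> tuple[tuple[tuple[int, str], ...], tuple[str, ...]]:
    """Split a matched span into repeat units and linkers.

    Mirrors the regex's choice policy (greedy unit, nearest next unit), which
    is exact on an already-matched span.
    """
    units: list[tuple[int, str]] = []
    linkers: list[str] = []
    pos = 0
    n = len(seq)
    unit = "RGG" if seq[pos : pos + 3] == "RGG" else "RG"
    units.append((offset + pos, unit))
    pos += len(unit)
    while pos < n:
        for lk in range(5):
            j = pos + lk
            if j + 1 < n and seq[j] == "R" and seq[j + 1] == "G":
                linkers.append(seq[pos:j])
                unit = "RGG" if seq[j : j + 3] == "RGG" else "RG"
                units.append((offset + j, unit))
                pos = j + len(unit)
                break
        else:  # pragma: no cover - impossible on a regex-matched span
            raise AssertionError(f"cannot decompose motif span {seq!r}")
    return tuple(units), tuple(linkers)


def find_rgg_motifs(protein: str, protein_id: str = "") -> list[RGGMotif]:
    """Maximal, non-overlapping RGG motifs in left-to-right order."""
    protein = protein.upper()
    out = []
    for m in _MOTIF_RE.finditer(protein):
        units, linkers = _decompose(m.group(), m.start())
        out.append(
            RGGMotif(
                protein_id=protein_id,
                start=m.start(),
                end=m.end(),
                sequence=m.group(),
                units=units,
                linkers=linkers,
            )
        )
    return out


def motif_features(m: RGGMotif) -> dict:
    """Repeat and linker descriptors of one motif.

    Returns counts of RG and RGG units, motif length, number/total/mean
    length of linkers, and the amino-acid composition of linker residues
    (empty dict when all linkers are empty).
    """
    linker_res = "".join(m.linkers)
    comp = {
        aa: linker_res.count(aa) / len(linker_res) for aa in sorted(set(linker_res))
    }
    n_linkers = len(m.linkers)
    total = len(linker_res)
    return {
        "n_rg": m.n_rg,
        "n_rgg": m.n_rgg,
        "n_units": len(m.units),
        "length": m.length,
        "n_linkers": n_linkers,
        "total_linker": total,
        "mean_linker": total / n_linkers if n_linkers else 0.0,
        "linker_composition": comp,
    }


def motif_cds_interval(m: RGGMotif) -> tuple[int, int]:
    """Half-open CDS-coordinate interval encoding the motif: [3*start, 3*end)."""
    return 3 * m.start, 3 * m.end


def _grammar_fullmatch(s: str) -> bool:
    """True iff the entire string is one RGG-grammar motif (>= 2 units)."""
    m = _MOTIF_RE.fullmatch(s)
    return m is not None


@lru_cache(maxsize=1)
def min_motif_length(max_probe: int = 6) -> int:
    """Analytic minimum motif length, found by exhaustive search.

    Enumerates every string over {R, G, A} up to ``max_probe`` residues and
    returns the length of the shortest full grammar match (4: ``RGRG``).
    """
    for n in range(1, max_probe + 1):
        for tup in itertools.product("RGA", repeat=n):
            if _grammar_fullmatch("".join(tup)):
                return n
    raise RuntimeError(f"no motif of length <= {max_probe} found")
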