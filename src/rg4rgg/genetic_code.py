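"""Standard and randomized genetic codes.

The analysis at the heart of this package asks whether the association between
RGG protein motifs and G-quadruplex-forming mRNA regions is a consequence of
the *structure* of the genetic code (arginine and glycine being encoded by
guanine-rich codons).  That question is answered by comparing the native code
against randomized codes, which requires three primitives implemented here:

* translation of a CDS under an arbitrary codon table,
* degeneracy-preserving random reassignment of the 61 sense codons
  (a permutation of sense codons; stop codons are fixed points),
* synonymous *recoding* of a CDS under such a permutation, which rewrites the
  nucleotide sequence while leaving the translated protein unchanged.

The internal nucleotide alphabet is DNA (``ACGT``); ``U`` is normalized to
``T`` on input so that interval arithmetic downstream never has to deal with
two alphabets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "STOP",
    "AMINO_ACIDS",
    "SENSE_CODONS",
    "ALL_CODONS",
    "CodonTable",
    "CodonPermutation",
    "Transcript",
    "ArgGlyAssignment",
    "standard_table",
    "translate",
    "guanine_content",
    "shuffle_codons",
    "enumerate_arg_gly_assignments",
    "recode",
    "normalize_nt",
    "TranslationWarning",
]

STOP = "*"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: all 64 trinucleotides, lexicographic over ACGT
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(_NT, repeat=3)
)

_NCBI1 = unambiguous_dna_by_id[1]
_STANDARD_MAP: dict[str, str] = {c: aa for c, aa in _NCBI1.forward_table.items()}
_STANDARD_MAP.update({c: STOP for c in _NCBI1.stop_codons})

#: the 61 protein-coding codons of the standard code, sorted
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ALL_CODONS if _STANDARD_MAP[c] != STOP)
)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_NCBI1.stop_codons))


class TranslationWarning(UserWarning):
    """Raised (as a warning) when a CDS translates with an internal stop."""


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: mapping of all 64 codons to amino acids or ``'*'``.

    Parameters
    ----------
    mapping
        Codon (DNA alphabet) -> one-letter amino acid, ``'*'`` for stop.
    label
        Free-text identifier.
    complete
        If True (default), require that every one of the 20 standard amino
        acids has at least one codon.  Reduced alphabets (e.g. the R/G/other
        tables used for arginine/glycine reassignment) set this to False.
    meta
        Optional annotations (e.g. ``native``/``gly_native`` flags).
    """

    mapping: Mapping[str, str]
    label: str = "table"
    complete: bool = True
    meta: Mapping[str, object] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if set(self.mapping) != set(ALL_CODONS):
            raise ValueError("codon table must cover all 64 trinucleotides")
        stops = [c for c, aa in self.mapping.items() if aa == STOP]
        if len(stops) != 3:
            raise ValueError(f"expected exactly 3 stop codons, got {len(stops)}")
        if self.complete:
            seen = set(self.mapping.values()) - {STOP}
            missing = set(AMINO_ACIDS) - seen
            if missing:
                raise ValueError(f"amino acids without codons: {sorted(missing)}")

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """Sorted codons assigned to ``aa`` (or to ``'*'``)."""
        return tuple(sorted(c for c, a in self.mapping.items() if a == aa))

    @property
    def degeneracy(self) -> dict[str, int]:
        """Number of codons per amino-acid symbol (stops excluded)."""
        out: dict[str, int] = {}
        for c, aa in self.mapping.items():
            if aa != STOP:
                out[aa] = out.get(aa, 0) + 1
        return out

    def byte_array(self) -> np.ndarray:
        """Length-65 uint8 lookup: codon index -> amino-acid byte.

        Index 64 holds ``'X'`` and is used for codons containing ``N``.
        """
        arr = np.empty(65, dtype=np.uint8)
        for i, codon in enumerate(ALL_CODONS):
            arr[i] = ord(self.mapping[codon])
        arr[64] = ord("X")
        return arr

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for codon in ALL_CODONS:
                fh.write(f"{codon}\t{self.mapping[codon]}\n")

    @classmethod
    def from_tsv(cls, path, label: str = "table", complete: bool = True) -> "CodonTable":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                codon, sym = line.split()
                mapping[normalize_nt(codon)] = sym
        return cls(mapping=mapping, label=label, complete=complete)


@lru_cache(maxsize=1)
def standard_table() -> CodonTable:
    """The standard genetic code (NCBI translation table 1)."""
    return CodonTable(mapping=dict(_STANDARD_MAP), label="standard")


def _codon_index(codon: str) -> int:
    """Index of a codon in :data:`ALL_CODONS`; 64 if it contains ``N``."""
    idx = 0
    for ch in codon:
        p = _NT.find(ch)
        if p < 0:
            return 64
        idx = idx * 4 + p
    return idx


def codon_indices(cds: str) -> np.ndarray:
    """Codon index array of a CDS (index 64 marks codons containing ``N``).

    Length must be a multiple of 3; raises ``ValueError`` otherwise.
    """
    seq = normalize_nt(cds)
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set(_NT) - {"N"}
    if bad:
        raise ValueError(f"unexpected nucleotide symbols: {sorted(bad)}")
    return np.fromiter(
        (_codon_index(seq[i : i + 3]) for i in range(0, len(seq), 3)),
        dtype=np.int64,
        count=len(seq) // 3,
    )


def translate(cds: str, table: CodonTable | None = None) -> str:
    """Translate a CDS; one symbol per codon, trailing stop dropped.

    Codons containing ``N`` translate to ``'X'``.  An internal stop under the
    given table is tolerated — it is kept as ``'*'`` (which can never be part
    of an RGG motif) and a :class:`TranslationWarning` is emitted.  This is
    required because randomized codes relocate stop assignments conceptually,
    so randomized translations of real CDS routinely contain internal stops.
    """
    table = table or standard_table()
    idx = codon_indices(cds)
    aa = table.byte_array()[idx].tobytes().decode("ascii")
    if aa.endswith(STOP):
        aa = aa[:-1]
    if STOP in aa:
        warnings.warn(
            "internal stop codon(s) in translation; kept as '*'",
            TranslationWarning,
            stacklevel=2,
        )
    return aa


def guanine_content(table: CodonTable, aa: str) -> float:
    """Mean guanine fraction of the codons assigned to ``aa``.

    For the standard code this gives 8/18 ~ 44% for arginine and
    9/12 = 75% for glycine, the compositional asymmetry the whole
    rG4/RGG coding relationship rests on.
    """
    codons = table.codons_for(aa)
    if not codons:
        raise ValueError(f"no codons assigned to {aa!r}")
    return float(np.mean([c.count("G") / 3 for c in codons]))


@dataclass(frozen=True)
class CodonPermutation:
    """A bijection over the 61 sense codons (stop codons are fixed points)."""

    mapping: Mapping[str, str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.mapping) != set(SENSE_CODONS):
            raise ValueError("permutation domain must be the 61 sense codons")
        if set(self.mapping.values()) != set(SENSE_CODONS):
            raise ValueError("permutation must be a bijection over sense codons")

    @classmethod
    def identity(cls) -> "CodonPermutation":
        return cls(mapping={c: c for c in SENSE_CODONS})

    def inverse(self) -> "CodonPermutation":
        return CodonPermutation(
            mapping={v: k for k, v in self.mapping.items()}, seed=self.seed
        )

    def induced_table(self, base: CodonTable | None = None) -> CodonTable:
        """Randomized code ``aa'(c) = aa(sigma(c))``.

        Because sigma is a bijection of sense codons, the induced table has
        exactly the native per-amino-acid codon-count profile.
        """
        base = base or standard_table()
        mapping = {c: base.mapping[c] for c in STOP_CODONS}
        for c in SENSE_CODONS:
            mapping[c] = base.mapping[self.mapping[c]]
        return CodonTable(mapping=mapping, label=f"shuffled(seed={self.seed})")

    def index_array(self) -> np.ndarray:
        """Length-65 codon-index lookup for sigma^-1 (used by :func:`recode`).

        Stop codons and ``N``-containing codons map to themselves.
        """
        arr = np.arange(65, dtype=np.int64)
        inv = self.inverse()
        for c_from, c_to in inv.mapping.items():
            arr[_codon_index(c_from)] = _codon_index(c_to)
        return arr

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in SENSE_CODONS:
                fh.write(f"{c}\t{self.mapping[c]}\n")

    @classmethod
    def from_tsv(cls, path) -> "CodonPermutation":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    a, b = line.split()
                    mapping[normalize_nt(a)] = normalize_nt(b)
        return cls(mapping=mapping)


def shuffle_codons(seed: int | np.random.Generator) -> CodonPermutation:
    """Uniformly random permutation of the 61 sense codons.

    Reproducible: the same integer seed always yields the same permutation.
    A ``numpy.random.Generator`` may be passed instead of a seed when drawing
    many permutations from one stream.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_rec = seed, None
    else:
        rng, seed_rec = np.random.default_rng(seed), int(seed)
    perm = rng.permutation(len(SENSE_CODONS))
    mapping = {SENSE_CODONS[i]: SENSE_CODONS[int(j)] for i, j in enumerate(perm)}
    return CodonPermutation(mapping=mapping, seed=seed_rec)


def recode(cds: str, perm: CodonPermutation) -> str:
    """Rewrite a CDS codon-by-codon with ``sigma^-1``.

    ``translate(recode(cds, perm), perm.induced_table())`` equals
    ``translate(cds, standard_table())`` position by position, so recoding
    changes the nucleotide sequence while keeping the protein fixed.  Stop
    codons (including a trailing stop) and ``N``-containing codons are left
    unchanged.
    """
    seq = normalize_nt(cds)
    idx = codon_indices(seq)
    lut = perm.index_array()
    out = []
    for i, j in zip(idx, lut[idx]):
        if i == 64:  # codon with N: passed through verbatim
            pos = len(out) * 3
            out.append(seq[pos : pos + 3])
        else:
            out.append(ALL_CODONS[int(j)])
    return "".join(out)


@dataclass(frozen=True)
class ArgGlyAssignment:
    """One assignment of Arg and Gly to native codon groups.

    The 20 per-amino-acid codon sets of the standard code are treated as
    indivisible boxes.  ``arg_source``/``gly_source`` name the amino acid
    whose native box now codes for R / G.  Residues other than R and G are
    irrelevant to the RGG grammar and are collapsed to a placeholder residue.
    """

    table: CodonTable
    arg_source: str
    gly_source: str
    native: bool
    gly_native: bool


def enumerate_arg_gly_assignments() -> list[ArgGlyAssignment]:
    """All 380 ways to assign Arg and Gly to two distinct native codon boxes.

    Ordered pairs of distinct groups: 20 * 19 = 380, i.e. 379 alternatives
    plus the native assignment (flagged ``native``).  ``gly_native`` marks
    the 19 assignments where glycine keeps its native box.
    """
    std = standard_table()
    groups = {aa: std.codons_for(aa) for aa in AMINO_ACIDS}
    out: list[ArgGlyAssignment] = []
    for arg_src in AMINO_ACIDS:
        for gly_src in AMINO_ACIDS:
            if arg_src == gly_src:
                continue
            mapping = {c: "A" for c in SENSE_CODONS}
            mapping.update({c: STOP for c in STOP_CODONS})
            for c in groups[arg_src]:
                mapping[c] = "R"
            for c in groups[gly_src]:
                mapping[c] = "G"
            native = arg_src == "R" and gly_src == "G"
            gly_native = gly_src == "G"
            table = CodonTable(
                mapping=mapping,
                label=f"arg<-{arg_src},gly<-{gly_src}",
                complete=False,
                meta={"native": native, "gly_native": gly_native},
            )
            out.append(
                ArgGlyAssignment(
                    table=table,
                    arg_source=arg_src,
                    gly_source=gly_src,
                    native=native,
                    gly_native=gly_native,
                )
            )
    return out


@dataclass
class Transcript:
    """One protein-coding transcript: CDS plus short UTR flanks.

    ``cds`` length must be divisible by 3 and may end in a stop codon; the
    flanks are the adjoining up-to-50-nt stretches of the untranslated
    regions, retained because quadruplex prediction is run on CDS +- flanks.
    Transcript-space coordinates used throughout the package run over
    ``utr5_flank + cds + utr3_flank``.
    """

    id: str
    cds: str
    utr5_flank: str = ""
    utr3_flank: str = ""

    MAX_FLANK = 50

    def __post_init__(self) -> None:
        self.cds = normalize_nt(self.cds)
        self.utr5_flank = normalize_nt(self.utr5_flank)
        self.utr3_flank = normalize_nt(self.utr3_flank)
        if len(self.cds) % 3:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")
        for name in ("utr5_flank", "utr3_flank"):
            if len(getattr(self, name)) > self.MAX_FLANK:
                raise ValueError(f"{self.id}: {name} longer than {self.MAX_FLANK} nt")
        self._protein: str | None = None

    @property
    def protein(self) -> str:
        """Translation of the CDS under the standard code (cached)."""
        if self._protein is None:
            self._protein = translate(self.cds)
        return self._protein

    @property
    def seq(self) -> str:
        """Full transcript-space sequence: 5' flank + CDS + 3' flank."""
        return self.utr5_flank + self.cds + self.utr3_flank

    @property
    def cds_span(self) -> tuple[int, int]:
        """Half-open CDS interval in transcript space."""
        start = len(self.utr5_flank)
        return start, start + len(self.cds)
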