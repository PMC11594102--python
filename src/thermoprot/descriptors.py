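"""The 14 protein descriptor encoders.

Each descriptor maps one validated amino-acid sequence to a fixed-width
real vector with deterministic, name-prefixed sub-features:

========  ====================================  ==================
name      family                                dimension
========  ====================================  ==================
AAC       residue composition                   20
DPC       dipeptide composition                 400
TPC       tripeptide composition                8000
GAAC      grouped residue composition           5
GDPC      grouped dipeptide composition         25
GTPC      grouped tripeptide composition        125
DDE       dipeptide deviation from expectation  400
CKSAAP    k-spaced residue pairs                400 * (k_max + 1)
CKSAAGP   k-spaced group pairs                  25 * (k_max + 1)
CTDC      property-group composition            39
CTDT      property-group transitions            39
CTDD      property-group distribution           195
CTriad    conjoint-triad counts                 343
KSCTriad  k-spaced conjoint triads              343 * (k_max + 1)
========  ====================================  ==================

Composition families (and every k-slice of the k-spaced pair families)
are frequency-normalized so each vector/slice sums to 1.  Conjoint-triad
slices are scaled by the maximum count in the slice (bounded features;
an all-zero slice stays zero).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from ._tables import (
    CODON_COUNTS,
    CODON_TOTAL,
    CONJOINT_TRIAD_CLASSES,
    CTD_PROPERTIES,
    RESIDUE_GROUPS,
)
from .sequence_io import AMINO_ACIDS, SequenceRecord

DESCRIPTOR_NAMES = (
    "AAC", "DPC", "TPC", "GAAC", "GDPC", "GTPC", "DDE",
    "CKSAAP", "CKSAAGP", "CTDC", "CTDT", "CTDD", "CTriad", "KSCTriad",
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_GROUP_NAMES = tuple(RESIDUE_GROUPS)
_N_GROUPS = len(_GROUP_NAMES)  # 5

# residue code -> 5-group index
_GROUP_OF = np.empty(20, dtype=np.int64)
for _gi, _g in enumerate(_GROUP_NAMES):
    for _a in RESIDUE_GROUPS[_g]:
        _GROUP_OF[_AA_INDEX[_a]] = _gi

# residue code -> 7-class conjoint-triad index
_TRIAD_OF = np.empty(20, dtype=np.int64)
for _ci, _cls in enumerate(CONJOINT_TRIAD_CLASSES):
    for _a in _cls:
        _TRIAD_OF[_AA_INDEX[_a]] = _ci

# residue code -> codon count
_CODONS = np.array([CODON_COUNTS[a] for a in AMINO_ACIDS], dtype=float)

_ENCODE_TABLE = bytes.maketrans(
    AMINO_ACIDS.encode(), bytes(range(len(AMINO_ACIDS)))
)


def sequence_codes(sequence: str) -> np.ndarray:
    """Map a validated sequence to integer residue codes 0..19."""
    raw = sequence.encode()
    translated = raw.translate(_ENCODE_TABLE)
    codes = np.frombuffer(translated, dtype=np.uint8).astype(np.int64)
    if codes.size and codes.max() >= 20:
        bad = sequence[int(np.argmax(codes >= 20))]
        raise ValueError(f"non-canonical residue {bad!r}; validate sequences first")
    return codes


@dataclass(frozen=True)
class DescriptorSpec:
    """A named descriptor with parameters, dimension and column names."""

    name: str
    params: dict = field(default_factory=dict)
    dimension: int = 0
    sub_feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.dimension != len(self.sub_feature_names):
            raise ValueError(
                f"{self.name}: dimension {self.dimension} != "
                f"{len(self.sub_feature_names)} sub-feature names"
            )


# default gap windows for the k-spaced families
DEFAULT_K = {"CKSAAP": 5, "CKSAAGP": 5, "KSCTriad": 2}


def _words(symbols: Sequence[str], order: int) -> list[str]:
    return ["".join(w) for w in itertools.product(symbols, repeat=order)]


def _names(name: str, k_max: int | None = None) -> tuple[str, ...]:
    aa = list(AMINO_ACIDS)
    if name == "AAC":
        return tuple(f"AAC.{a}" for a in aa)
    if name == "DPC":
        return tuple(f"DPC.{w}" for w in _words(aa, 2))
    if name == "TPC":
        return tuple(f"TPC.{w}" for w in _words(aa, 3))
    if name == "GAAC":
        return tuple(f"GAAC.{g}" for g in _GROUP_NAMES)
    if name == "GDPC":
        return tuple(f"GDPC.{a}.{b}" for a, b in itertools.product(_GROUP_NAMES, repeat=2))
    if name == "GTPC":
        return tuple(
            f"GTPC.{a}.{b}.{c}" for a, b, c in itertools.product(_GROUP_NAMES, repeat=3)
        )
    if name == "DDE":
        return tuple(f"DDE.{w}" for w in _words(aa, 2))
    if name == "CKSAAP":
        return tuple(
            f"CKSAAP.{w}.k{k}" for k in range(k_max + 1) for w in _words(aa, 2)
        )
    if name == "CKSAAGP":
        return tuple(
            f"CKSAAGP.{a}.{b}.k{k}"
            for k in range(k_max + 1)
            for a, b in itertools.product(_GROUP_NAMES, repeat=2)
        )
    if name == "CTDC":
        return tuple(
            f"CTDC.{p}.G{g}" for p in CTD_PROPERTIES for g in (1, 2, 3)
        )
    if name == "CTDT":
        return tuple(
            f"CTDT.{p}.{t}" for p in CTD_PROPERTIES for t in ("G1G2", "G1G3", "G2G3")
        )
    if name == "CTDD":
        return tuple(
            f"CTDD.{p}.G{g}.p{q}"
            for p in CTD_PROPERTIES
            for g in (1, 2, 3)
            for q in (0, 25, 50, 75, 100)
        )
    if name == "CTriad":
        return tuple(
            f"CTriad.{a + 1}{b + 1}{c + 1}"
            for a, b, c in itertools.product(range(7), repeat=3)
        )
    if name == "KSCTriad":
        return tuple(
            f"KSCTriad.{a + 1}{b + 1}{c + 1}.k{k}"
            for k in range(k_max + 1)
            for a, b, c in itertools.product(range(7), repeat=3)
        )
    raise KeyError(f"unknown descriptor {name!r}; choose from {DESCRIPTOR_NAMES}")


def get_spec(name: str, **params) -> DescriptorSpec:
    """Build the :class:`DescriptorSpec` for a descriptor name.

    ``k_max`` is accepted (and defaulted) for the gapped families and
    rejected for the others.
    """
    if name not in DESCRIPTOR_NAMES:
        raise KeyError(f"unknown descriptor {name!r}; choose from {DESCRIPTOR_NAMES}")
    if name in DEFAULT_K:
        k_max = int(params.pop("k_max", DEFAULT_K[name]))
        if k_max < 0:
            raise ValueError("k_max must be >= 0")
        if params:
            raise TypeError(f"{name}: unexpected params {sorted(params)}")
        names = _names(name, k_max)
        return DescriptorSpec(name, {"k_max": k_max}, len(names), names)
    if params:
        raise TypeError(f"{name}: unexpected params {sorted(params)}")
    names = _names(name)
    return DescriptorSpec(name, {}, len(names), names)


def block_names(spec: DescriptorSpec) -> tuple[str, ...]:
    """Ordered, stable sub-feature names of a descriptor block."""
    return spec.sub_feature_names


# ---------------------------------------------------------------------------
# encoders


def encode_composition_family(order: int, grouped: bool, sequence: str) -> np.ndarray:
    """Frequency of contiguous length-``order`` words.

    Over the residue alphabet (AAC/DPC/TPC) or the 5-group alphabet
    (GAAC/GDPC/GTPC).  Counts are divided by ``len - order + 1`` so the
    vector sums to 1.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    codes = sequence_codes(sequence)
    n = codes.size
    if n < order:
        raise ValueError(f"sequence length {n} < minimum {order} for order-{order} composition")
    base = _N_GROUPS if grouped else 20
    if grouped:
        codes = _GROUP_OF[codes]
    word = codes[: n - order + 1].copy()
    for j in range(1, order):
        word = word * base + codes[j : n - order + 1 + j]
    counts = np.bincount(word, minlength=base**order).astype(float)
    return counts / (n - order + 1)


def encode_kspaced_pairs(grouped: bool, k_max: int, sequence: str) -> np.ndarray:
    """Ordered pair frequencies (s[i], s[i+k+1]) for each gap k in 0..k_max.

    Each k-slice is normalized by its pair count ``len - k - 1`` and so
    sums to 1.  The k=0 slice equals DPC (or GDPC).
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    codes = sequence_codes(sequence)
    n = codes.size
    if n < k_max + 2:
        raise ValueError(
            f"sequence length {n} too short for k_max={k_max}; minimum length is {k_max + 2}"
        )
    base = _N_GROUPS if grouped else 20
    if grouped:
        codes = _GROUP_OF[codes]
    slices = []
    for k in range(k_max + 1):
        pairs = codes[: n - k - 1] * base + codes[k + 1 :]
        counts = np.bincount(pairs, minlength=base * base).astype(float)
        slices.append(counts / (n - k - 1))
    return np.concatenate(slices)


def encode_dde(sequence: str) -> np.ndarray:
    """Dipeptide deviation from expected mean.

    For dipeptide (i, j): observed fraction Dc, codon-derived
    theoretical mean Tm = (C_i/61)(C_j/61) and variance
    Tv = Tm (1 - Tm) / (L - 1); the feature is (Dc - Tm) / sqrt(Tv).
    """
    codes = sequence_codes(sequence)
    n = codes.size
    if n < 2:
        raise ValueError(f"sequence length {n} < minimum 2 for DDE")
    dc = encode_composition_family(2, grouped=False, sequence=sequence)
    p = _CODONS / CODON_TOTAL
    tm = np.outer(p, p).ravel()
    tv = tm * (1.0 - tm) / (n - 1)
    return (dc - tm) / np.sqrt(tv)


def encode_ctd(part: str, sequence: str) -> np.ndarray:
    """Composition (C), Transition (T) or Distribution (D) encoding.

    Per property: C = fractions of residues in G1/G2/G3; T = fractions
    of adjacent pairs whose groups differ, split by unordered group pair,
    denominator ``len - 1``; D = for each group the positions (percent of
    sequence length) of its first, 25%, 50%, 75% and last residue
    (quantile occurrence index ``ceil(q * n_group)``), 0 if absent.
    """
    if part not in ("C", "T", "D"):
        raise ValueError("part must be 'C', 'T' or 'D'")
    codes = sequence_codes(sequence)
    n = codes.size
    if n < 1 or (part == "T" and n < 2):
        raise ValueError(f"sequence length {n} too short for CTD{part}")
    out: list[float] = []
    for prop, groups in CTD_PROPERTIES.items():
        gidx = np.empty(20, dtype=np.int64)
        for g, members in enumerate(groups):
            for a in members:
                gidx[_AA_INDEX[a]] = g
        seq_groups = gidx[codes]
        if part == "C":
            counts = np.bincount(seq_groups, minlength=3).astype(float)
            out.extend(counts / n)
        elif part == "T":
            a, b = seq_groups[:-1], seq_groups[1:]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            trans = [
                np.count_nonzero((lo == 0) & (hi == 1)),
                np.count_nonzero((lo == 0) & (hi == 2)),
                np.count_nonzero((lo == 1) & (hi == 2)),
            ]
            out.extend(t / (n - 1) for t in trans)
        else:
            for g in range(3):
                pos = np.flatnonzero(seq_groups == g) + 1  # 1-based positions
                if pos.size == 0:
                    out.extend([0.0] * 5)
                    continue
                m = pos.size
                for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                    idx = max(1, int(np.ceil(q * m)))
                    out.append(pos[idx - 1] / n * 100.0)
    return np.asarray(out, dtype=float)


def encode_ctriad(k_max: int, sequence: str) -> np.ndarray:
    """Conjoint-triad counts (class triples s[i], s[i+k+1], s[i+2k+2]).

    Each k-slice is divided by its maximum count (an all-zero slice
    stays zero).  ``k_max=0`` is plain CTriad.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    codes = sequence_codes(sequence)
    n = codes.size
    min_len = 2 * k_max + 3
    if n < min_len:
        raise ValueError(
            f"sequence length {n} too short for k_max={k_max}; minimum length is {min_len}"
        )
    classes = _TRIAD_OF[codes]
    slices = []
    for k in range(k_max + 1):
        span = 2 * k + 2
        a = classes[: n - span]
        b = classes[k + 1 : n - span + k + 1]
        c = classes[span:]
        triples = (a * 7 + b) * 7 + c
        counts = np.bincount(triples, minlength=343).astype(float)
        mx = counts.max()
        slices.append(counts / mx if mx > 0 else counts)
    return np.concatenate(slices)


def _dispatch(spec: DescriptorSpec) -> Callable[[str], np.ndarray]:
    name = spec.name
    k = spec.params.get("k_max")
    table: dict[str, Callable[[str], np.ndarray]] = {
        "AAC": lambda s: encode_composition_family(1, False, s),
        "DPC": lambda s: encode_composition_family(2, False, s),
        "TPC": lambda s: encode_composition_family(3, False, s),
        "GAAC": lambda s: encode_composition_family(1, True, s),
        "GDPC": lambda s: encode_composition_family(2, True, s),
        "GTPC": lambda s: encode_composition_family(3, True, s),
        "DDE": encode_dde,
        "CKSAAP": lambda s: encode_kspaced_pairs(False, k, s),
        "CKSAAGP": lambda s: encode_kspaced_pairs(True, k, s),
        "CTDC": lambda s: encode_ctd("C", s),
        "CTDT": lambda s: encode_ctd("T", s),
        "CTDD": lambda s: encode_ctd("D", s),
        "CTriad": lambda s: encode_ctriad(0, s),
        "KSCTriad": lambda s: encode_ctriad(k, s),
    }
    return table[name]


def encode(spec: DescriptorSpec, record: SequenceRecord | str) -> np.ndarray:
    """Encode one sequence under one descriptor spec."""
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    vec = _dispatch(spec)(seq)
    assert vec.shape == (spec.dimension,)
    return vec


def encode_many(spec: DescriptorSpec, sequences: Iterable[str]) -> np.ndarray:
    """Encode an iterable of sequences into a (n, dimension) matrix."""
    fn = _dispatch(spec)
    rows = [fn(s) for s in sequences]
    if not rows:
        return np.empty((0, spec.dimension))
    return np.vstack(rows)
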