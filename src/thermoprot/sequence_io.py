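"""Reading, validating, filtering and partitioning protein sequence sets.

Sequences are plain strings over the 20-letter canonical amino-acid
alphabet.  Validation is deliberately strict: any record containing a
non-canonical symbol (``B J O U X Z``, gaps, stops, digits, whitespace)
is rejected outright rather than imputed, so every downstream encoder
can assume a clean alphabet.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from sklearn.model_selection import train_test_split

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Minimum accepted sequence length; shorter records are filtered out.
MIN_LENGTH = 20


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with identifier and optional binary label.

    label 1 = thermophilic (positive class), 0 = non-thermophilic.
    """

    id: str
    sequence: str
    label: Optional[int] = None
    source: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r} in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> Optional[np.ndarray]:
        """Label vector, or None if any record is unlabelled."""
        if any(r.label is None for r in self.records):
            return None
        return np.array([r.label for r in self.records], dtype=int)

    def with_labels(self, labels: dict[str, int]) -> "SequenceSet":
        """Return a copy whose records carry labels looked up by id."""
        missing = [r.id for r in self.records if r.id not in labels]
        if missing:
            raise KeyError(f"no label for ids: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        recs = [replace(r, label=int(labels[r.id])) for r in self.records]
        return SequenceSet(recs, name=self.name)


@dataclass(frozen=True)
class FilterRejection:
    id: str
    rule: str  # "r1" empty / "r2" too short / "r3" non-canonical
    detail: str


@dataclass
class FilterLog:
    """Per-record outcome of :func:`validate_and_filter`."""

    n_input: int = 0
    n_accepted: int = 0
    rejections: list[FilterRejection] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = [f"{r.id}\t{r.rule}" for r in self.rejections]
        return "\n".join(lines) + ("\n" if lines else "")


def read_fasta(path: str | Path, name: Optional[str] = None) -> SequenceSet:
    """Read a (wrapped or unwrapped) multi-record FASTA into a SequenceSet.

    Sequences are uppercased; no validation beyond FASTA syntax is done
    here — use :func:`validate_and_filter` afterwards.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"FASTA record with empty header in {path}")
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), source=str(path)))
    return SequenceSet(records, name=name or path.stem)


def write_fasta(s: SequenceSet, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for r in s:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``id<TAB>label`` TSV into a dict."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'id<TAB>label', got {line!r}")
            lab = int(parts[1])
            if lab not in (0, 1):
                raise ValueError(f"{path}:{ln}: label must be 0 or 1, got {lab}")
            labels[parts[0]] = lab
    return labels


def write_labels(s: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in s:
            if r.label is None:
                raise ValueError(f"record {r.id} has no label")
            fh.write(f"{r.id}\t{r.label}\n")


def _first_violation(seq: str) -> Optional[tuple[str, str]]:
    # rule order matters: r1 (empty) -> r2 (short) -> r3 (alphabet)
    if len(seq) == 0:
        return "r1", "empty sequence"
    if len(seq) < MIN_LENGTH:
        return "r2", f"length {len(seq)} < {MIN_LENGTH}"
    bad = next((c for c in seq if c not in _AA_SET), None)
    if bad is not None:
        return "r3", f"non-canonical character {bad!r}"
    return None


def validate_and_filter(s: SequenceSet) -> tuple[SequenceSet, FilterLog]:
    """Apply the cleaning rules and return (accepted set, log).

    Rules, in order: r1 non-empty; r2 length >= 20; r3 canonical
    20-letter alphabet only.  Filtering is total — nothing raises; every
    rejection is logged with the first rule violated.
    """
    log = FilterLog(n_input=len(s))
    accepted = []
    for r in s:
        seq = r.sequence.upper()
        violation = _first_violation(seq)
        if violation is None:
            accepted.append(replace(r, sequence=seq))
        else:
            rule, detail = violation
            log.rejections.append(FilterRejection(id=r.id, rule=rule, detail=detail))
    log.n_accepted = len(accepted)
    return SequenceSet(accepted, name=s.name), log


def is_valid_sequence(seq: str) -> bool:
    return _first_violation(seq.upper()) is None


def check_disjoint(train: SequenceSet, test: SequenceSet) -> list[tuple[str, str]]:
    """Return all (train id, test id) pairs with identical sequence strings."""
    by_seq: dict[str, list[str]] = {}
    for r in train:
        by_seq.setdefault(r.sequence, []).append(r.id)
    pairs = []
    for t in test:
        for train_id in by_seq.get(t.sequence, ()):
            pairs.append((train_id, t.id))
    return pairs


def split_holdout(
    s: SequenceSet, test_fraction: float, seed: int
) -> tuple[SequenceSet, SequenceSet]:
    """Stratified-by-label random holdout split, reproducible given seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = s.labels
    if y is None:
        raise ValueError("split_holdout requires a fully labelled SequenceSet")
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError(f"each class needs >= 2 members for a stratified split, got {counts.tolist()}")
    idx = np.arange(len(s))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    train = SequenceSet([s[i] for i in train_idx], name=f"{s.name}.train")
    test = SequenceSet([s[i] for i in test_idx], name=f"{s.name}.test")
    return train, test
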