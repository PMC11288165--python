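"""Reading, validating and writing labeled DNA sequence sets.

The on-disk carrier is plain multi-record FASTA plus a two-column
tab-separated labels file mapping record id to class name. When no labels
file is given, deflines must follow the ``>id|label`` convention. Sequences
are upper-cased on ingest; characters outside {A, C, G, T} (Ns, IUPAC
ambiguity codes) are retained in storage and dealt with at featurization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGT")


class SequenceIOError(ValueError):
    """Malformed FASTA or labels input."""


class LabelingError(SequenceIOError):
    """A record is missing a class label, or labels are inconsistent."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    label: str


@dataclass
class LabeledSequenceSet:
    """DNA sequences with per-record class labels.

    ``class_names`` preserves the order of first appearance and defines the
    integer class encoding used downstream.
    """

    records: list[SequenceRecord]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        order: list[str] = []
        for rec in self.records:
            if rec.id in seen_ids:
                raise SequenceIOError(f"duplicate record id {rec.id!r}")
            seen_ids.add(rec.id)
            if not rec.sequence:
                raise SequenceIOError(f"record {rec.id!r} has an empty sequence")
            if rec.sequence != rec.sequence.upper():
                raise SequenceIOError(
                    f"record {rec.id!r} not upper-cased; construct via from_records"
                )
            if rec.label not in order:
                order.append(rec.label)
        if not self.class_names:
            self.class_names = order
        else:
            missing = [l for l in order if l not in self.class_names]
            if missing:
                raise LabelingError(f"labels {missing} absent from class_names")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "LabeledSequenceSet":
        """Build a set from ``(id, sequence, label)`` triples, normalizing case."""
        recs = [
            SequenceRecord(rid, seq.upper(), label) for rid, seq, label in records
        ]
        return cls(records=recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for r in self.records:
            h.update(f"{r.id}\t{r.label}\t{r.sequence}\n".encode())
        return h.hexdigest()


@dataclass
class ValidationReport:
    n_records: int
    n_invalid_chars: dict[str, int]
    alphabet_found: set[str]
    per_class_counts: dict[str, int]


def read_labels(path: str | Path) -> dict[str, str]:
    """Parse a two-column TSV ``id<TAB>label`` map; a leading ``id\\tlabel``
    header row is ignored. Duplicate ids and malformed rows are rejected."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SequenceIOError(
                    f"{path}: row {lineno} has {len(parts)} columns, expected 2"
                )
            rid, label = parts
            if lineno == 1 and rid.lower() == "id" and label.lower() == "label":
                continue
            if rid in labels:
                raise SequenceIOError(f"{path}: duplicate id {rid!r} at row {lineno}")
            labels[rid] = label
    return labels


def read_fasta(
    path: str | Path, labels: Mapping[str, str] | None = None
) -> LabeledSequenceSet:
    """Read a FASTA file into a :class:`LabeledSequenceSet`.

    Label precedence: explicit ``labels`` map first; otherwise the defline
    must follow the ``>id|label`` convention.
    """
    path = Path(path)
    _check_fasta_shape(path)
    triples: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        seq = str(rec.seq)
        if labels is not None:
            if "|" in rid and rid not in labels:
                rid = rid.split("|", 1)[0]
            if rid not in labels:
                raise LabelingError(f"no label for record {rid!r} in labels map")
            label = labels[rid]
        else:
            if "|" not in rid:
                raise LabelingError(
                    f"record {rid!r}: no labels file and defline lacks 'id|label'"
                )
            rid, label = rid.split("|", 1)
        if not seq:
            raise SequenceIOError(f"record {rid!r} has an empty sequence")
        triples.append((rid, seq, label))
    if not triples:
        raise SequenceIOError(f"{path}: no FASTA records found")
    return LabeledSequenceSet.from_records(triples)


def _check_fasta_shape(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequenceIOError(
                    f"{path}: line {lineno}: expected '>' defline, got {line[:20]!r}"
                )
            return
    raise SequenceIOError(f"{path}: empty file")


def write_fasta(
    sset: LabeledSequenceSet,
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    width: int = 60,
) -> None:
    """Write FASTA (wrapped at ``width`` columns) and optionally a labels TSV.

    When ``labels_path`` is omitted, labels are encoded in deflines as
    ``>id|label`` so that ``read_fasta`` round-trips without a side file.
    """
    with open(fasta_path, "w") as fh:
        for rec in sset.records:
            header = rec.id if labels_path is not None else f"{rec.id}|{rec.label}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    if labels_path is not None:
        write_labels(sset, labels_path)


def write_labels(sset: LabeledSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec in sset.records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def validate_sequences(sset: LabeledSequenceSet) -> ValidationReport:
    """Count non-ACGT characters per record and tally classes; purely
    observational, never mutates the input."""
    if not sset.records:
        raise SequenceIOError("cannot validate an empty sequence set")
    invalid: dict[str, int] = {}
    alphabet: set[str] = set()
    per_class: dict[str, int] = {name: 0 for name in sset.class_names}
    for rec in sset.records:
        alphabet.update(rec.sequence)
        invalid[rec.id] = sum(1 for ch in rec.sequence if ch not in DNA_ALPHABET)
        per_class[rec.label] += 1
    return ValidationReport(
        n_records=len(sset.records),
        n_invalid_chars=invalid,
        alphabet_found=alphabet,
        per_class_counts=per_class,
    )
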