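"""FASTA / label-table I/O, sequence validation and numeric encoding.

Sequences are scored over the 20 standard amino acids plus ``X`` (unknown).
Ambiguous one-letter codes (B, Z, J, U, O) are normalised to ``X`` and encoded
as zero vectors, which are neutral under the model's first linear layer.

Coordinate convention used throughout the package: the cleavage site ``cs`` is
the 1-based index of the LAST residue of the targeting peptide, so cleavage
occurs between ``cs`` and ``cs + 1``.  Relative positions around the cleavage
bond use -1 for the last peptide residue and +1 for the first mature residue;
there is no position 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Fixed residue column order for all numeric encodings.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Ambiguous / non-standard codes normalised to X (selenocysteine U included:
#: it is NOT remapped to C).
AMBIGUOUS_TO_X = str.maketrans({c: "X" for c in "BZJUO"})

CLASSES = ("noTP", "SP", "mTP", "cTP", "luTP")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}
#: Classes that carry a cleavage site, in the order of the dedicated
#: attention heads (rows 0-3 of the attention matrix).
CS_CLASSES = ("SP", "mTP", "cTP", "luTP")

GROUPS = ("plant", "nonplant")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line number."""


class EncodingError(ValueError):
    """Raised when a residue outside the allowed alphabet is encountered."""


def _blosum62_matrix() -> np.ndarray:
    """20x20 BLOSUM62 block in the package's fixed column order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.float32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out


BLOSUM62 = _blosum62_matrix()


@dataclass
class ProteinRecord:
    """One protein sequence with optional supervision.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header up to the first whitespace).
    sequence : str
        Residues over ``ALPHABET`` plus ``X`` after normalisation.
    group : str
        ``"plant"`` or ``"nonplant"``.
    label : str, optional
        One of ``CLASSES``.
    cs : int, optional
        1-based index of the last targeting-peptide residue.
    valid_for_training : bool
        Cleared when N-terminal truncation cuts off the cleavage site.
    """

    id: str
    sequence: str
    group: str = "nonplant"
    label: Optional[str] = None
    cs: Optional[int] = None
    valid_for_training: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().translate(AMBIGUOUS_TO_X)
        self.validate()

    def validate(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa != "X" and aa not in RESIDUE_INDEX:
                raise EncodingError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {pos}"
                )
        if self.group not in GROUPS:
            raise ValueError(f"record {self.id!r}: unknown group {self.group!r}")
        if self.label is not None:
            if self.label not in CLASS_INDEX:
                raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")
            if self.label in CS_CLASSES:
                if self.cs is None:
                    raise ValueError(
                        f"record {self.id!r}: class {self.label} requires a cleavage site"
                    )
                if not (1 <= self.cs < len(self.sequence)):
                    raise ValueError(
                        f"record {self.id!r}: cs={self.cs} outside [1, {len(self.sequence) - 1}]"
                    )
            elif self.cs is not None:
                raise ValueError(f"record {self.id!r}: noTP record must not carry a cs")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EncodedBatch:
    """Padded numeric view of a list of records.

    ``features`` holds one BLOSUM62 row per residue (zeros for ``X`` and for
    padding); ``mask`` is True on real residues; ``group_vec`` is 1.0 for
    plant, 0.0 for nonplant; ``cs_targets`` uses 0-based positions with -1 as
    the no-cleavage sentinel.
    """

    features: np.ndarray  # (B, L, 20) float32
    lengths: np.ndarray  # (B,) int64
    mask: np.ndarray  # (B, L) bool
    group_vec: np.ndarray  # (B, 1) float32
    ids: list
    cs_targets: Optional[np.ndarray] = None  # (B,) int64, -1 sentinel
    class_targets: Optional[np.ndarray] = None  # (B,) int64

    def __len__(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _prescan_fasta(text: str) -> None:
    """Validate FASTA structure, reporting the offending line number."""
    header_line = None
    seen_seq = False
    saw_any = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            saw_any = True
            if stripped == ">":
                raise FastaParseError(f"line {lineno}: FASTA header has no identifier")
            if header_line is not None and not seen_seq:
                raise FastaParseError(
                    f"line {header_line}: FASTA entry has an empty sequence"
                )
            header_line = lineno
            seen_seq = False
        else:
            if header_line is None:
                raise FastaParseError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            seen_seq = True
    if not saw_any:
        raise FastaParseError("line 1: no FASTA entries found")
    if header_line is not None and not seen_seq:
        raise FastaParseError(f"line {header_line}: FASTA entry has an empty sequence")


def read_fasta(path, group: str = "nonplant") -> list:
    """Read a FASTA file into :class:`ProteinRecord` objects (input order kept).

    Ids are taken from the header up to the first whitespace; sequences are
    upper-cased and ambiguous codes mapped to X (U is mapped to X, not C).
    """
    with open(path) as fh:
        text = fh.read()
    _prescan_fasta(text)
    records = []
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq), group=group))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, path, "fasta-2line")


# ---------------------------------------------------------------------------
# Label sidecar (TSV: id, label, cs; cs empty for noTP)
# ---------------------------------------------------------------------------

def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    required = {"id", "label", "cs"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return df


def write_labels(records: Iterable[ProteinRecord], path) -> None:
    rows = [
        {"id": r.id, "label": r.label, "cs": "" if r.cs is None else r.cs}
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "label", "cs"]).to_csv(path, sep="\t", index=False)


def attach_labels(records: Sequence[ProteinRecord], labels: pd.DataFrame) -> list:
    """Return new records carrying the label/cs columns of the sidecar table."""
    table = labels.set_index("id")
    out = []
    for r in records:
        if r.id not in table.index:
            raise KeyError(f"no label row for record {r.id!r}")
        row = table.loc[r.id]
        cs = row["cs"]
        cs = None if (pd.isna(cs) or cs == "") else int(cs)
        out.append(replace(r, label=str(row["label"]), cs=cs))
    return out


# ---------------------------------------------------------------------------
# Truncation and encoding
# ---------------------------------------------------------------------------

def truncate_n_terminal(record: ProteinRecord, max_len: int = 200) -> ProteinRecord:
    """Keep the first ``max_len`` residues (the model's input window).

    A record whose cleavage site falls outside the window keeps its annotation
    but is flagged ``valid_for_training=False``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(record.sequence) <= max_len:
        return record
    if record.cs is not None and record.cs >= max_len:
        # keep the full sequence so the (now unreachable) cs stays consistent
        return replace(record, valid_for_training=False)
    return replace(record, sequence=record.sequence[:max_len])


def encode_batch(records: Sequence[ProteinRecord], max_len: int = 200) -> EncodedBatch:
    """Encode records as padded BLOSUM62 feature tensors.

    Rows of ``features`` are the BLOSUM62 matrix rows of each residue in the
    column order ``ALPHABET``; ``X`` encodes as the zero vector.  Targets are
    filled when every record carries a label.
    """
    if not records:
        raise ValueError("encode_batch: empty record list")
    lengths = np.array([min(len(r), max_len) for r in records], dtype=np.int64)
    L = int(lengths.max())
    B = len(records)
    features = np.zeros((B, L, 20), dtype=np.float32)
    mask = np.zeros((B, L), dtype=bool)
    group_vec = np.zeros((B, 1), dtype=np.float32)
    for i, r in enumerate(records):
        seq = r.sequence[: lengths[i]]
        for t, aa in enumerate(seq):
            if aa == "X":
                continue
            j = RESIDUE_INDEX.get(aa)
            if j is None:  # pragma: no cover - caught by record validation
                raise EncodingError(
                    f"record {r.id!r}: invalid residue {aa!r} at position {t + 1}"
                )
            features[i, t] = BLOSUM62[j]
        mask[i, : lengths[i]] = True
        group_vec[i, 0] = 1.0 if r.group == "plant" else 0.0

    cs_targets = None
    class_targets = None
    if all(r.label is not None for r in records):
        class_targets = np.array([CLASS_INDEX[r.label] for r in records], dtype=np.int64)
        cs_targets = np.array(
            [(r.cs - 1) if r.cs is not None else -1 for r in records], dtype=np.int64
        )
        for i, r in enumerate(records):
            if cs_targets[i] >= lengths[i]:
                raise ValueError(
                    f"record {r.id!r}: cs={r.cs} beyond encoded length {lengths[i]}"
                )
    return EncodedBatch(
        features=features,
        lengths=lengths,
        mask=mask,
        group_vec=group_vec,
        ids=[r.id for r in records],
        cs_targets=cs_targets,
        class_targets=class_targets,
    )
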