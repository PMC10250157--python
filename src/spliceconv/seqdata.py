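"""Sequence windows, one-hot encoding, and dataset assembly.

A splice-site dataset is a collection of fixed-length (default 400 nt)
sequence windows, each labeled as a true or false acceptor/donor site.  The
annotated site dinucleotide (AG for acceptors, GT for donors) sits at a fixed
window offset (default 300), so a classifier sees both the site itself and
its flanking context.  Nucleotides are one-hot encoded as Z x 4 matrices in
column order (A, C, G, T) with N as the all-zero row.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, DatasetError, DecodingError, EncodingError

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
BASE_ORDER = "ACGT"
WINDOW_LEN = 400
SITE_OFFSET = 300
CONSENSUS = {"acceptor": "AG", "donor": "GT"}

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

SiteType = Literal["acceptor", "donor"]
Label = Literal["true_site", "false_site"]

# base -> row index; N encodes to the zero row
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_ENCODE_LUT = np.zeros((256, 4), dtype=np.float32)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b), _i] = 1.0


def normalize_sequence(bases: str) -> str:
    """Uppercase and map IUPAC ambiguity codes (other than N) to N.

    Characters outside the IUPAC nucleotide alphabet raise
    :class:`EncodingError` naming the offending position.
    """
    up = bases.upper()
    out = []
    n_mapped = 0
    for i, ch in enumerate(up):
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            out.append("N")
            n_mapped += 1
        else:
            raise EncodingError(
                f"invalid character {ch!r} at position {i}: not a nucleotide code"
            )
    if n_mapped:
        logger.warning("mapped %d IUPAC ambiguity codes to N", n_mapped)
    return "".join(out)


@dataclass
class NucleotideSequence:
    """A named DNA sequence over the normalized alphabet {A, C, G, T, N}."""

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if any(ch not in ALPHABET for ch in self.bases):
            self.bases = normalize_sequence(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            str(Seq(self.bases).reverse_complement()), id=self.id
        )


@dataclass
class SpliceWindow:
    """One labeled fixed-length window around a candidate splice site."""

    sequence: NucleotideSequence
    site_type: SiteType
    label: Label
    organism: str = ""
    source_coords: tuple[str, int, str] | None = None  # (contig, 0-based start, strand)

    @property
    def bases(self) -> str:
        return self.sequence.bases


@dataclass
class SpliceDataset:
    """An ordered collection of same-site-type windows with a declared ratio."""

    windows: list[SpliceWindow]
    distribution: Literal["balanced", "imbalanced", "custom"] = "custom"
    metadata: dict = field(default_factory=dict)

    @property
    def ratio(self) -> tuple[int, int]:
        """(n_true, n_false) counts."""
        n_true = sum(1 for w in self.windows if w.label == "true_site")
        return n_true, len(self.windows) - n_true

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def labels(self) -> np.ndarray:
        """Integer labels: 1 = true_site (positive class), 0 = false_site."""
        return np.fromiter(
            (1 if w.label == "true_site" else 0 for w in self.windows),
            dtype=np.int64,
            count=len(self.windows),
        )

    def encode(self) -> np.ndarray:
        """One-hot encode all windows into an (n, Z, 4) float32 tensor."""
        if not self.windows:
            return np.zeros((0, 0, 4), dtype=np.float32)
        return np.stack([one_hot_encode(w.sequence) for w in self.windows])

    def subset(self, indices: Sequence[int]) -> "SpliceDataset":
        return SpliceDataset(
            [self.windows[i] for i in indices],
            distribution="custom",
            metadata=dict(self.metadata),
        )


def one_hot_encode(seq: NucleotideSequence | str) -> np.ndarray:
    """Encode a sequence as a Z x 4 matrix, columns (A, C, G, T), N -> zero row."""
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    for i, ch in enumerate(bases):
        if ch not in ALPHABET:
            raise EncodingError(f"cannot encode character {ch!r} at position {i}")
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[arr].copy()


def one_hot_decode(mat: np.ndarray) -> NucleotideSequence:
    """Invert :func:`one_hot_encode`; zero rows decode to N."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise DecodingError(f"expected a Z x 4 matrix, got shape {mat.shape}")
    out = []
    for i, row in enumerate(mat):
        hot = np.flatnonzero(row == 1)
        if row.sum() == 0 and hot.size == 0:
            out.append("N")
        elif hot.size == 1 and row.sum() == 1:
            out.append(BASE_ORDER[hot[0]])
        else:
            raise DecodingError(
                f"row {i} ({row.tolist()}) is neither a basis vector nor zero"
            )
    return NucleotideSequence("".join(out))


# ---------------------------------------------------------------------------
# window extraction


def read_annotations(path: str | Path) -> list[dict]:
    """Read a site-annotation TSV: contig, pos (0-based), strand, site_type, label."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["contig", "pos", "strand", "site_type", "label"]
        if header != expected:
            raise AnnotationError(
                f"bad annotation header {header!r}; expected {expected!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise AnnotationError(
                    f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            contig, pos, strand, site_type, label = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-integer pos {pos!r}") from exc
            if strand not in "+-":
                raise AnnotationError(f"line {lineno}: strand must be + or -")
            if site_type not in ("acceptor", "donor"):
                raise AnnotationError(f"line {lineno}: bad site_type {site_type!r}")
            if label not in ("true_site", "false_site", "true", "false"):
                raise AnnotationError(f"line {lineno}: bad label {label!r}")
            rows.append(
                {
                    "contig": contig,
                    "pos": pos_i,
                    "strand": strand,
                    "site_type": site_type,
                    "label": "true_site" if label in ("true", "true_site") else "false_site",
                }
            )
    return rows


def extract_windows(
    genome: Iterable[NucleotideSequence],
    annotations: list[dict],
    window_len: int = WINDOW_LEN,
    site_offset: int = SITE_OFFSET,
    organism: str = "",
) -> SpliceDataset:
    """Cut fixed-length windows around annotated sites.

    Each annotation gives the 0-based position of the first base of the site
    dinucleotide; the emitted window places that base at ``site_offset``.
    Minus-strand sites are reverse-complemented first so every stored window
    reads 5'->3' with the consensus in forward orientation.  Sites whose
    window would overrun a contig edge are skipped and counted.
    """
    if window_len <= site_offset + 1:
        raise DatasetError("window_len must exceed site_offset + 1")
    contigs = OrderedDict((s.id, s) for s in genome)
    windows: list[SpliceWindow] = []
    skipped = 0
    for ann in annotations:
        if ann["contig"] not in contigs:
            raise AnnotationError(f"unknown contig {ann['contig']!r}")
        contig = contigs[ann["contig"]]
        if ann["strand"] == "+":
            start = ann["pos"] - site_offset
            end = start + window_len
            if start < 0 or end > len(contig):
                skipped += 1
                continue
            bases = contig.bases[start:end]
        else:
            # minus strand: pos is the first site base in transcript
            # orientation, i.e. the higher genomic coordinate of the
            # dinucleotide [pos-1, pos]; after reverse complementing, genomic
            # position g lands at window index (end - 1 - g), so pos sits at
            # site_offset when end = pos + 1 + site_offset
            end = ann["pos"] + 1 + site_offset
            start = end - window_len
            if start < 0 or end > len(contig):
                skipped += 1
                continue
            bases = str(Seq(contig.bases[start:end]).reverse_complement())
        windows.append(
            SpliceWindow(
                sequence=NucleotideSequence(bases),
                site_type=ann["site_type"],
                label=ann["label"],
                organism=organism,
                source_coords=(ann["contig"], start, ann["strand"]),
            )
        )
    if skipped:
        logger.info("skipped %d sites whose window overran a contig edge", skipped)
    ds = SpliceDataset(windows, distribution="custom")
    ds.metadata.update(
        {"window_len": window_len, "site_offset": site_offset, "skipped": skipped}
    )
    return ds


def build_dataset(
    true_pool: Sequence[SpliceWindow],
    false_pool: Sequence[SpliceWindow],
    distribution: Literal["balanced", "imbalanced"],
    total: int = 10_000,
    seed: int = 0,
) -> SpliceDataset:
    """Sample a balanced (1:1) or imbalanced (3:1 true:false) dataset.

    Sampling is without replacement and reproducible under ``seed``.
    """
    if distribution == "balanced":
        if total % 2:
            raise DatasetError("balanced total must be divisible by 2")
        n_true = n_false = total // 2
    elif distribution == "imbalanced":
        if total % 4:
            raise DatasetError("imbalanced total must be divisible by 4")
        n_true, n_false = 3 * total // 4, total // 4
    else:
        raise DatasetError(f"unknown distribution {distribution!r}")
    if len(true_pool) < n_true:
        raise DatasetError(
            f"true pool has {len(true_pool)} windows, {n_true} requested "
            f"(shortfall {n_true - len(true_pool)})"
        )
    if len(false_pool) < n_false:
        raise DatasetError(
            f"false pool has {len(false_pool)} windows, {n_false} requested "
            f"(shortfall {n_false - len(false_pool)})"
        )
    rng = np.random.default_rng(seed)
    t_idx = rng.choice(len(true_pool), size=n_true, replace=False)
    f_idx = rng.choice(len(false_pool), size=n_false, replace=False)
    windows = [true_pool[i] for i in t_idx] + [false_pool[i] for i in f_idx]
    ds = SpliceDataset(windows, distribution=distribution)
    ds.metadata.update({"seed": seed, "n_true": n_true, "n_false": n_false})
    return ds


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA into normalized sequences."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise DatasetError(f"FASTA parse error in {path}: {exc}") from exc
    if not records:
        raise DatasetError(f"no FASTA records found in {path}")
    return [NucleotideSequence(str(r.seq), id=r.id) for r in records]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id or f"seq{i}", description="") for i, s in enumerate(seqs)]
    SeqIO.write(records, str(path), "fasta")


DATASET_COLUMNS = ["id", "organism", "site_type", "label", "sequence"]


def write_dataset(dataset: SpliceDataset, path: str | Path) -> None:
    """Serialize a dataset as TSV plus a ``<path>.meta`` key-value sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(DATASET_COLUMNS) + "\n")
        for i, w in enumerate(dataset.windows):
            wid = w.sequence.id or f"w{i:06d}"
            fh.write(f"{wid}\t{w.organism}\t{w.site_type}\t{w.label}\t{w.bases}\n")
    n_true, n_false = dataset.ratio
    meta = {
        "distribution": dataset.distribution,
        "n_true": n_true,
        "n_false": n_false,
        **dataset.metadata,
    }
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")


def read_dataset(path: str | Path) -> SpliceDataset:
    """Read a dataset TSV (and its sidecar, if present)."""
    path = Path(path)
    windows: list[SpliceWindow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DATASET_COLUMNS:
            raise DatasetError(
                f"bad dataset header {header!r} in {path}; expected {DATASET_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if not line.endswith("\n") :
                raise DatasetError(f"{path}: truncated record at line {lineno}")
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise DatasetError(
                    f"{path} line {lineno}: expected 5 fields, got {len(parts)}"
                )
            wid, organism, site_type, label, seq = parts
            if site_type not in ("acceptor", "donor") or label not in (
                "true_site",
                "false_site",
            ):
                raise DatasetError(f"{path} line {lineno}: bad site_type/label")
            windows.append(
                SpliceWindow(
                    sequence=NucleotideSequence(seq, id=wid),
                    site_type=site_type,  # type: ignore[arg-type]
                    label=label,  # type: ignore[arg-type]
                    organism=organism,
                )
            )
    metadata: dict = {}
    distribution = "custom"
    meta_path = path.with_suffix(path.suffix + ".meta")
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                metadata[k] = v
        distribution = metadata.pop("distribution", "custom")
    return SpliceDataset(windows, distribution=distribution, metadata=metadata)
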