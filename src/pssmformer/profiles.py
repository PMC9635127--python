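"""PSSM profile and dataset I/O.

A position-specific scoring matrix (PSSM) summarises, for each position of a
protein sequence, the log-odds of observing each of the 20 amino acids there
relative to background frequencies. PSI-BLAST emits one ASCII PSSM per query
protein; this module reads and writes that dialect, reads FASTA, assembles
labelled datasets via a CSV manifest, and provides seeded stratified
train/test and k-fold partitioners.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

#: Fixed PSI-BLAST residue column order for the log-odds block.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"
_RESIDUE_SET = set(RESIDUE_ORDER)
N_RESIDUES = 20


class PSSMFormatError(ValueError):
    """Raised when a PSSM or FASTA stream does not match the expected format."""


@dataclass
class PSSMProfile:
    """One protein's PSSM: an N x 20 log-odds matrix plus bookkeeping.

    Attributes
    ----------
    id : str
        Protein identifier (unique within a dataset).
    residues : str
        The amino-acid sequence, one letter per matrix row.
    scores : np.ndarray
        Shape (N, 20) float array of log-odds, columns in :data:`RESIDUE_ORDER`.
    label : int | None
        1 = adaptor protein, 0 = non-adaptor, None = unlabelled.
    """

    id: str
    residues: str
    scores: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_RESIDUES:
            raise ValueError(
                f"scores must be N x {N_RESIDUES}, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues) or len(self.residues) < 1:
            raise ValueError(
                f"{self.scores.shape[0]} score rows for {len(self.residues)} residues"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSMProfile):
            return NotImplemented
        return (
            self.id == other.id
            and self.residues == other.residues
            and self.label == other.label
            and np.array_equal(self.scores, other.scores)
        )


@dataclass
class LabeledDataset:
    """An ordered collection of labelled profiles with unique identifiers."""

    profiles: list[PSSMProfile]
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [p.id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate profile identifiers in dataset")
        for p in self.profiles:
            if p.label not in (0, 1):
                raise ValueError(f"profile {p.id!r} has no binary label")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[PSSMProfile]:
        return iter(self.profiles)

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.profiles], dtype=int)

    def ids(self) -> list[str]:
        return [p.id for p in self.profiles]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.profiles[i] for i in indices], name=name or self.name
        )

    @property
    def n_pos(self) -> int:
        return int(self.labels().sum())

    @property
    def n_neg(self) -> int:
        return len(self) - self.n_pos


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _is_residue_header(tokens: list[str]) -> bool:
    # The PSI-BLAST header line lists the 20 residue letters (once for the
    # log-odds block, usually again for the percentage block).
    return (
        len(tokens) >= N_RESIDUES
        and all(len(t) == 1 and t in _RESIDUE_SET for t in tokens[:N_RESIDUES])
        and len(set(tokens[:N_RESIDUES])) == N_RESIDUES
    )


def parse_pssm(stream: TextIO, id: str = "") -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM into a :class:`PSSMProfile`.

    Only the first 20-column block (log-odds) is kept; the percentage block
    and the trailing per-row statistics are discarded, as are footer lines
    (K/lambda estimates). Files whose residue header permutes the standard
    column order are re-mapped onto :data:`RESIDUE_ORDER`; a file with no
    residue header is rejected.

    Raises
    ------
    PSSMFormatError
        On a missing header, an empty body, a residue letter outside the
        20-letter alphabet, or a body row without 40 (or 42, with the two
        trailing statistics) numeric columns — the message names the
        offending 1-based line number.
    """
    header_perm: np.ndarray | None = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    in_body = False

    for lineno, raw in enumerate(stream, start=1):
        tokens = raw.split()
        if not tokens:
            if in_body:
                break  # blank line ends the body; what follows is footer
            continue
        if header_perm is None:
            if _is_residue_header(tokens):
                order = "".join(tokens[:N_RESIDUES])
                header_perm = np.array(
                    [order.index(a) for a in RESIDUE_ORDER], dtype=int
                )
            continue
        # body row: index, residue letter, >= 40 numbers
        if not tokens[0].lstrip("-").isdigit():
            if in_body:
                break  # footer (lambda/K lines) reached
            continue
        if len(tokens) < 2 or len(tokens[1]) != 1:
            raise PSSMFormatError(f"line {lineno}: malformed PSSM body row")
        aa = tokens[1].upper()
        if aa not in _RESIDUE_SET:
            raise PSSMFormatError(
                f"line {lineno}: residue {tokens[1]!r} outside the 20-letter alphabet"
            )
        numbers = tokens[2:]
        if len(numbers) not in (2 * N_RESIDUES, 2 * N_RESIDUES + 2):
            raise PSSMFormatError(
                f"line {lineno}: expected 40 numeric columns "
                f"(plus optional 2 statistics), found {len(numbers)}"
            )
        try:
            logodds = np.array([float(v) for v in numbers[:N_RESIDUES]])
        except ValueError as exc:
            raise PSSMFormatError(f"line {lineno}: non-numeric score: {exc}") from None
        rows.append(logodds[header_perm])
        residues.append(aa)
        in_body = True

    if header_perm is None:
        raise PSSMFormatError("no residue-order header line found")
    if not rows:
        raise PSSMFormatError("PSSM body is empty")
    return PSSMProfile(id=id, residues="".join(residues), scores=np.vstack(rows))


def write_pssm(profile: PSSMProfile, stream: TextIO) -> None:
    """Write *profile* in a PSI-BLAST-compatible ASCII dialect.

    Log-odds are written as given; the percentage block is written as zeros
    and the footer is omitted, so each body row carries 42 whitespace
    separated tokens (index, residue, 40 numbers).
    """
    stream.write("\n")
    stream.write("Last position-specific scoring matrix computed\n")
    letters = " ".join(RESIDUE_ORDER)
    stream.write(f"           {letters}  {letters}\n")
    for i, (aa, row) in enumerate(zip(profile.residues, profile.scores), start=1):
        cells = " ".join(_fmt_score(v) for v in row)
        zeros = " ".join("0" for _ in range(N_RESIDUES))
        stream.write(f"{i:5d} {aa}  {cells}  {zeros}\n")
    stream.write("\n")


def _fmt_score(v: float) -> str:
    # integers round-trip exactly; non-integer scores keep full precision
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_pssm_file(path: str | Path, label: int | None = None) -> PSSMProfile:
    path = Path(path)
    with open(path) as fh:
        prof = parse_pssm(fh, id=path.stem)
    if label is not None:
        prof = replace(prof, label=label)
    return prof


def write_pssm_file(profile: PSSMProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        write_pssm(profile, fh)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: TextIO) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs, order preserved.

    The identifier is the first whitespace-delimited token of the header;
    sequences are uppercased. Sequence data before the first header is a
    format error.
    """
    # peek: any non-blank content before the first '>' is malformed
    lines = stream.read().splitlines()
    for line in lines:
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise PSSMFormatError("sequence data before first FASTA header")
        break
    records = []
    for title, seq in SimpleFastaParser(iter(lines)):
        records.append((title.split()[0] if title.split() else "", seq.upper()))
    return records


# ---------------------------------------------------------------------------
# Dataset manifest (CSV: id,path,label)
# ---------------------------------------------------------------------------

def write_manifest(rows: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "label"])
        for row in rows:
            writer.writerow(row)


def load_dataset(manifest: str | Path, name: str | None = None) -> LabeledDataset:
    """Load a labelled dataset from a ``id,path,label`` CSV manifest.

    Relative paths are resolved against the manifest's directory.
    """
    manifest = Path(manifest)
    base = manifest.parent
    profiles = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "path", "label"} <= set(
            reader.fieldnames
        ):
            raise PSSMFormatError("manifest must have columns id,path,label")
        for row in reader:
            label = row["label"].strip()
            if label not in ("0", "1"):
                raise PSSMFormatError(
                    f"manifest entry {row['id']!r} has non-binary label {label!r}"
                )
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            prof = read_pssm_file(p, label=int(label))
            prof = replace(prof, id=row["id"])
            profiles.append(prof)
    return LabeledDataset(profiles, name=name or manifest.stem)


# ---------------------------------------------------------------------------
# Partitioners
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratified_split(
    dataset: LabeledDataset, test_fraction: float = 0.2, seed: int = 42
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded stratified train/test split.

    Per class, ``round(n_class * test_fraction)`` members (half away from
    zero) go to the test set, chosen by a seeded shuffle. Raises if either
    split would lose a class entirely.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = dataset.labels()
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size == 0:
            raise ValueError(f"dataset has no members of class {cls}")
        n_test = _round_half_away(members.size * test_fraction)
        if n_test == 0 or n_test == members.size:
            raise ValueError(
                f"test_fraction {test_fraction} empties class {cls} in one split"
            )
        perm = rng.permutation(members.size)
        test_idx.extend(members[perm[:n_test]])
        train_idx.extend(members[perm[n_test:]])
    train_idx.sort()
    test_idx.sort()
    return (
        dataset.subset(train_idx, name=f"{dataset.name}-train"),
        dataset.subset(test_idx, name=f"{dataset.name}-test"),
    )


def kfold_stratified(
    dataset: LabeledDataset, k: int = 5, seed: int = 42
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Seeded stratified k-fold partition as ``(train, validation)`` pairs.

    Validation folds partition the dataset; within each class the fold sizes
    differ by at most one (members are dealt round-robin after a seeded
    shuffle). Raises if any class has fewer than *k* members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = dataset.labels()
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        if members.size < k:
            raise ValueError(f"class {cls} has {members.size} members, fewer than k={k}")
        perm = rng.permutation(members.size)
        for j, idx in enumerate(members[perm]):
            fold_members[j % k].append(int(idx))
    folds = []
    for f in range(k):
        val = sorted(fold_members[f])
        train = sorted(i for g in range(k) if g != f for i in fold_members[g])
        folds.append(
            (
                dataset.subset(train, name=f"{dataset.name}-fold{f}-train"),
                dataset.subset(val, name=f"{dataset.name}-fold{f}-val"),
            )
        )
    return folds
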