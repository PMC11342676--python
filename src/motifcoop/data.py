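"""Sequence input: BED peaks, FASTA extraction, one-hot encoding, splits.

Coordinates are 0-based half-open throughout (BED convention).  Sequences are
one-hot encoded as A:[1,0,0,0], C:[0,1,0,0], G:[0,0,1,0], T:[0,0,0,1]; an N
encodes as the all-zero row.  Train/test partitioning is by chromosome, with
chr1, chr8 and chr18 held out by default; synthetic sequences receive
pseudo-chromosome labels round-robin so the same rule applies to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MAX_SEQ_LEN = 1000

DEFAULT_HELDOUT = frozenset({"chr1", "chr8", "chr18"})

#: pseudo-chromosome cycle for synthetic sequences (mouse-style autosomes)
PSEUDO_CHROMS = tuple(f"chr{i}" for i in range(1, 20))

_CODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = -1
_CODE[ord("n")] = -1

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def one_hot(seq: str) -> np.ndarray:
    """len x 4 one-hot matrix; N rows are all-zero; case-insensitive."""
    codes = _CODE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    if np.any(codes == -2):
        bad = sorted({c for c in seq if _CODE[ord(c) if ord(c) < 256 else 0] == -2})
        raise ValueError(f"invalid characters in sequence: {bad}")
    out = np.zeros((len(seq), 4), dtype=np.uint8)
    valid = codes >= 0
    out[np.nonzero(valid)[0], codes[valid]] = 1
    return out


def decode_one_hot(onehot: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero rows decode to N."""
    onehot = np.asarray(onehot)
    bases = np.array(list("ACGT"))
    idx = onehot.argmax(axis=1)
    chars = bases[idx]
    chars[onehot.sum(axis=1) == 0] = "N"
    return "".join(chars)


@dataclass(frozen=True)
class EncodedSequence:
    """A labelled sequence with its one-hot encoding and genomic provenance."""

    id: str
    label: str  # "positive" | "negative"
    seq: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    onehot: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if len(self.seq) > MAX_SEQ_LEN:
            raise ValueError(
                f"sequence {self.id} is {len(self.seq)} bp; inputs up to "
                f"{MAX_SEQ_LEN} bp are supported")
        if self.onehot is None:
            object.__setattr__(self, "onehot", one_hot(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EncodedDataset:
    """Labelled sequences plus a chromosome-aware train/test partition."""

    sequences: list[EncodedSequence]
    train_idx: np.ndarray
    test_idx: np.ndarray
    heldout_chroms: frozenset[str] = DEFAULT_HELDOUT

    def __post_init__(self):
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train and test index sets overlap")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
        for idx in (self.train_idx, self.test_idx):
            labels = {self.sequences[i].label for i in idx}
            if labels != {"positive", "negative"}:
                raise ValueError("each split must contain both classes")
        for i in train:
            s = self.sequences[i]
            if s.chrom is not None and s.chrom in self.heldout_chroms:
                raise ValueError(
                    f"sequence {s.id} on held-out chromosome {s.chrom} in train set")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def seq_len(self) -> int:
        return len(self.sequences[0])

    def onehot_array(self, idx=None) -> np.ndarray:
        seqs = self.sequences if idx is None else [self.sequences[i] for i in idx]
        return np.stack([s.onehot for s in seqs])

    def labels(self, idx=None) -> np.ndarray:
        seqs = self.sequences if idx is None else [self.sequences[i] for i in idx]
        return np.array([1 if s.label == "positive" else 0 for s in seqs])

    def ids(self, idx=None) -> list[str]:
        seqs = self.sequences if idx is None else [self.sequences[i] for i in idx]
        return [s.id for s in seqs]


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) intervals from a BED file, in file order."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated "
                                 f"columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return intervals


def resize_peaks(intervals: list[tuple[str, int, int]],
                 size: int = 200) -> list[tuple[str, int, int]]:
    """Center each interval on its midpoint and fix its width to ``size``.

    Intervals that would extend below coordinate 0 are dropped (count logged).
    """
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    out, dropped = [], 0
    for chrom, start, end in intervals:
        mid = (start + end) // 2
        new_start = mid - size // 2
        if new_start < 0:
            dropped += 1
            continue
        out.append((chrom, new_start, new_start + size))
    if dropped:
        logger.info("resize_peaks: dropped %d interval(s) extending below 0", dropped)
    return out


def extract_peak_sequences(intervals, fasta_path, label: str = "positive",
                           max_n_fraction: float = 0.10) -> list[EncodedSequence]:
    """Extract interval sequences from an indexed FASTA.

    Windows with >= ``max_n_fraction`` N bases are dropped (count logged).
    """
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    out, dropped = [], 0
    for i, (chrom, start, end) in enumerate(intervals):
        seq = str(genome[chrom][start:end]).upper()
        if seq.count("N") >= max_n_fraction * len(seq):
            dropped += 1
            continue
        out.append(EncodedSequence(id=f"{chrom}:{start}-{end}", label=label,
                                   seq=seq, chrom=chrom, start=start, end=end))
    if dropped:
        logger.info("extract_peak_sequences: dropped %d N-rich window(s)", dropped)
    return out


def random_sequence(rng: np.random.Generator, length: int,
                    background: np.ndarray) -> str:
    codes = rng.choice(4, size=length, p=background)
    return "".join("ACGT"[c] for c in codes)


def generate_negatives(n: int, length: int,
                       background: np.ndarray | None = None,
                       seed: int | np.random.Generator = 0,
                       genome_path=None, exclude=None, pad: int = 200,
                       assign_chroms: bool = True) -> list[EncodedSequence]:
    """Generate ``n`` negative sequences of ``length`` bp.

    Without a genome, bases are drawn i.i.d. from ``background`` and
    pseudo-chromosomes assigned round-robin.  With ``genome_path``, windows
    are sampled uniformly from the genome, excluding ``exclude`` intervals
    padded by ``pad`` bp and N-rich windows.  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genome_path is None:
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        out = []
        for i in range(n):
            chrom = PSEUDO_CHROMS[i % len(PSEUDO_CHROMS)] if assign_chroms else None
            out.append(EncodedSequence(
                id=f"neg_{i}", label="negative",
                seq=random_sequence(rng, length, background), chrom=chrom))
        return out
    return _sample_genomic_negatives(n, length, rng, genome_path, exclude, pad)


def _sample_genomic_negatives(n, length, rng, genome_path, exclude, pad):
    from pyfaidx import Fasta

    genome = Fasta(str(genome_path))
    chroms = [c for c in genome.keys()]
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    usable = [c for c, s in zip(chroms, sizes) if s >= length]
    if not usable:
        raise ValueError("no chromosome long enough for negative sampling")
    sizes = np.array([len(genome[c]) for c in usable], dtype=float)
    excl: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in (exclude or []):
        excl.setdefault(chrom, []).append((start - pad, end + pad))
    out, attempts = [], 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not sample enough negative windows")
        c = usable[int(rng.choice(len(usable), p=sizes / sizes.sum()))]
        start = int(rng.integers(0, len(genome[c]) - length + 1))
        end = start + length
        if any(s < end and start < e for s, e in excl.get(c, [])):
            continue
        seq = str(genome[c][start:end]).upper()
        if seq.count("N") >= 0.10 * length:
            continue
        out.append(EncodedSequence(id=f"neg_{len(out)}", label="negative",
                                   seq=seq, chrom=c, start=start, end=end))
    return out


def split_by_chromosome(sequences: list[EncodedSequence],
                        heldout: frozenset[str] | set[str] = DEFAULT_HELDOUT,
                        ) -> EncodedDataset:
    """Partition sequences into train/test by chromosome.

    Sequences on held-out chromosomes go to the test split.  Sequences
    without a chromosome label are partitioned deterministically in
    proportion to the positive test fraction, preserving class balance.
    """
    heldout = frozenset(heldout)
    with_chrom = [i for i, s in enumerate(sequences) if s.chrom is not None]
    train = [i for i in with_chrom if sequences[i].chrom not in heldout]
    test = [i for i in with_chrom if sequences[i].chrom in heldout]
    nochrom = [i for i, s in enumerate(sequences) if s.chrom is None]
    if nochrom:
        if with_chrom:
            frac = len(test) / len(with_chrom)
        else:
            frac = len(heldout) / len(PSEUDO_CHROMS)
        stride = max(1, round(1 / frac)) if frac > 0 else len(nochrom) + 1
        for j, i in enumerate(nochrom):
            (test if j % stride == 0 else train).append(i)
    if not train or not test:
        raise ValueError(
            f"empty {'train' if not train else 'test'} split; held-out "
            f"chromosomes {sorted(heldout)} cover too "
            f"{'many' if not train else 'few'} sequences")
    return EncodedDataset(sequences=list(sequences),
                          train_idx=np.array(sorted(train)),
                          test_idx=np.array(sorted(test)),
                          heldout_chroms=heldout)
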