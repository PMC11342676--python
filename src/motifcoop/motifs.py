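"""Motif library handling: PFMs, log-odds PSSMs, score thresholds, redundancy.

A motif is represented by its position frequency matrix (PFM, raw base counts
per column) from which a base-2 log-odds position-specific score matrix (PSSM)
is derived against an i.i.d. background.  Each motif carries the score
threshold whose tail probability under the background model is at most a
chosen p-value (1e-4 by default), computed exactly over a discretized score
grid, and the PSSM of its reverse complement.  The library doubles as the
fixed filter bank of the convolutional scanner: filter ``k`` is motif ``k``
on the forward strand and filter ``k + n_motifs`` its reverse complement.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
#: row permutation implementing A<->T, C<->G
_RC_ROWS = np.array([3, 2, 1, 0])

UNIFORM_BACKGROUND = np.full(4, 0.25)

DEFAULT_PVALUE = 1e-4
DEFAULT_GRANULARITY = 1e-3


class JasparParseError(ValueError):
    """Raised when a JASPAR-format motif file cannot be parsed."""


def build_pssm(pfm: np.ndarray, background: np.ndarray = UNIFORM_BACKGROUND,
               pseudocount: float | None = None) -> np.ndarray:
    """Base-2 log-odds matrix from a 4xL count matrix.

    ``pssm[b, j] = log2((pfm[b, j] + pseudo_j) / column_total_j / background[b])``

    ``pseudocount=None`` adds 0.01 x the column total to every cell of that
    column; a scalar is used verbatim for every cell.  Raising a count can
    only raise that cell's score (monotonicity).
    """
    pfm = np.asarray(pfm, dtype=float)
    background = np.asarray(background, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError(f"pfm must be 4xL, got shape {pfm.shape}")
    if np.any(pfm < 0):
        raise ValueError("pfm counts must be nonnegative")
    if np.any(background <= 0):
        raise ValueError("background probabilities must be positive")
    totals = pfm.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("pfm has a column with zero total count")
    if pseudocount is None:
        pseudo = 0.01 * totals
    else:
        pseudo = np.full_like(totals, float(pseudocount))
    if np.any((pfm.min(axis=0) + pseudo) <= 0):
        raise ValueError("zero count with zero pseudocount gives -inf score")
    return np.log2((pfm + pseudo[None, :]) / totals[None, :] / background[:, None])


def reverse_complement(pssm: np.ndarray) -> np.ndarray:
    """Score matrix of the reverse-complement motif.

    Rows A<->T and C<->G are swapped and columns reversed; applying it twice
    returns the input.
    """
    pssm = np.asarray(pssm)
    if pssm.ndim != 2 or pssm.shape[0] != 4:
        raise ValueError(f"pssm must be 4xL, got shape {pssm.shape}")
    return pssm[_RC_ROWS][:, ::-1]


def score_distribution(pssm: np.ndarray, background: np.ndarray = UNIFORM_BACKGROUND,
                       granularity: float = DEFAULT_GRANULARITY,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of window scores under the i.i.d. background.

    Each PSSM cell is rounded to the nearest multiple of ``granularity``;
    the per-column score distributions are then convolved over an integer
    grid, which is exact for the discretized scores.  Returns
    ``(scores, probabilities)`` with scores ascending.
    """
    background = np.asarray(background, dtype=float)
    s_int = np.rint(np.asarray(pssm, dtype=float) / granularity).astype(np.int64)
    lo = 0
    dist = np.array([1.0])
    for j in range(s_int.shape[1]):
        col = s_int[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(dist.size + (cmax - cmin), dtype=float)
        for b in range(4):
            off = int(col[b]) - cmin
            new[off:off + dist.size] += dist * background[b]
        dist = new
        lo += cmin
    scores = (lo + np.arange(dist.size)) * granularity
    return scores, dist


def score_threshold(pssm: np.ndarray, pvalue: float = DEFAULT_PVALUE,
                    background: np.ndarray = UNIFORM_BACKGROUND,
                    granularity: float = DEFAULT_GRANULARITY) -> float:
    """Smallest discretized score ``t`` with ``P(score >= t) <= pvalue``.

    If ``pvalue`` is below the probability of even the single best word, the
    maximum achievable score is returned with a warning (no score satisfies
    the bound).
    """
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    scores, probs = score_distribution(pssm, background, granularity)
    if pvalue == 1:
        return float(scores[probs > 0][0])
    # survival[i] = P(score >= scores[i]); candidate thresholds are the
    # achievable scores (mass points), lowest qualifying one wins
    survival = np.cumsum(probs[::-1])[::-1]
    ok = (survival <= pvalue) & (probs > 0)
    if not np.any(ok):
        warnings.warn(
            "requested p-value is smaller than the best word's probability; "
            "returning the maximum achievable score", stacklevel=2)
        return float(scores[probs > 0][-1])
    return float(scores[np.argmax(ok)])


def information_content(pfm: np.ndarray) -> float:
    """Total information content in bits, summed over columns (uniform bg)."""
    freqs = np.asarray(pfm, dtype=float)
    freqs = freqs / freqs.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return float((2.0 + h.sum(axis=0)).sum())


@dataclass(frozen=True)
class MotifModel:
    """A named motif: counts, log-odds scores, threshold, reverse complement."""

    id: str
    name: str
    pfm: np.ndarray
    pssm: np.ndarray
    rc_pssm: np.ndarray
    threshold: float

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def information_content(self) -> float:
        return information_content(self.pfm)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.pfm, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.pssm.max(axis=0).sum())


@dataclass(frozen=True)
class MotifLibrary:
    """Ordered, uniquely-named motif collection sharing one background model."""

    motifs: tuple[MotifModel, ...]
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pvalue: float = DEFAULT_PVALUE

    def __post_init__(self):
        ids = [m.id for m in self.motifs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate motif ids in library: {dupes}")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, key) -> MotifModel:
        if isinstance(key, str):
            for m in self.motifs:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.motifs[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.motifs]

    @property
    def max_length(self) -> int:
        return max(m.length for m in self.motifs)

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([m.threshold for m in self.motifs])

    @property
    def motif_lengths(self) -> np.ndarray:
        return np.array([m.length for m in self.motifs])

    def filter_tensor(self) -> np.ndarray:
        """Fixed convolution filter bank, shape ``(2*n_motifs, 4, W)``.

        ``W`` is the library's maximum motif length.  Shorter motifs are
        left-padded with zero-score columns so that every motif's last column
        sits at the filter's last column: the scan index of a window is then
        the base-pair coordinate at which the motif *ends*, for every motif.
        Zero columns never change a window's score.  Filter ``k`` is motif
        ``k`` forward, filter ``k + n_motifs`` its reverse complement.
        """
        w = self.max_length
        k = len(self.motifs)
        filters = np.zeros((2 * k, 4, w))
        for i, m in enumerate(self.motifs):
            filters[i, :, w - m.length:] = m.pssm
            filters[k + i, :, w - m.length:] = m.rc_pssm
        return filters

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [m.id for m in self.motifs],
            "name": [m.name for m in self.motifs],
            "length": [m.length for m in self.motifs],
            "threshold": [m.threshold for m in self.motifs],
        })

    def manifest_hash(self) -> str:
        text = self.manifest().to_csv(index=False)
        return hashlib.sha256(text.encode()).hexdigest()


def make_motif(motif_id: str, name: str, pfm: np.ndarray,
               background: np.ndarray = UNIFORM_BACKGROUND,
               pseudocount: float | None = None,
               pvalue: float = DEFAULT_PVALUE,
               granularity: float = DEFAULT_GRANULARITY) -> MotifModel:
    pfm = np.asarray(pfm, dtype=float)
    pssm = build_pssm(pfm, background, pseudocount)
    return MotifModel(
        id=motif_id, name=name, pfm=pfm, pssm=pssm,
        rc_pssm=reverse_complement(pssm),
        threshold=score_threshold(pssm, pvalue, background, granularity),
    )


def make_library(records: list[tuple[str, str, np.ndarray]],
                 background: np.ndarray = UNIFORM_BACKGROUND,
                 pseudocount: float | None = None,
                 pvalue: float = DEFAULT_PVALUE,
                 granularity: float = DEFAULT_GRANULARITY) -> MotifLibrary:
    """Build a library from ``(id, name, pfm)`` records, preserving order."""
    motifs = tuple(make_motif(i, n, p, background, pseudocount, pvalue, granularity)
                   for i, n, p in records)
    return MotifLibrary(motifs=motifs, background=np.asarray(background, float),
                        pvalue=pvalue)


def parse_jaspar(path, background: np.ndarray = UNIFORM_BACKGROUND,
                 pseudocount: float | None = None,
                 pvalue: float = DEFAULT_PVALUE,
                 granularity: float = DEFAULT_GRANULARITY) -> MotifLibrary:
    """Parse a JASPAR-format text file into a :class:`MotifLibrary`.

    Records are kept in file order and counts preserved exactly.  Malformed
    records raise :class:`JasparParseError` naming the file and the record.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise JasparParseError(f"{path}: empty motif file")
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:  # biopython raises bare ValueError/KeyError
        raise JasparParseError(f"{path}: malformed JASPAR record ({exc})") from exc
    records = []
    for rec in parsed:
        pfm = np.array([rec.counts[b] for b in BASES], dtype=float)
        motif_id = rec.matrix_id or rec.name
        if pfm.size == 0 or pfm.shape[1] == 0:
            raise JasparParseError(f"{path}: record {motif_id!r} has no counts")
        records.append((motif_id, rec.name or motif_id, pfm))
    if not records:
        raise JasparParseError(f"{path}: no motif records found")
    return make_library(records, background, pseudocount, pvalue, granularity)


def write_jaspar(library: MotifLibrary, path) -> None:
    """Write a library back to JASPAR text format (exact counts)."""
    def fmt(x: float) -> str:
        return f"{int(x)}" if float(x).is_integer() else f"{x}"

    with open(path, "w") as fh:
        for m in library:
            fh.write(f">{m.id} {m.name}\n")
            for b, row in zip(BASES, m.pfm):
                fh.write(f"{b} [ " + " ".join(fmt(v) for v in row) + " ]\n")


def _frequency_matrix(motif: MotifModel) -> np.ndarray:
    return motif.pfm / motif.pfm.sum(axis=0, keepdims=True)


def best_offset_correlation(freq_a: np.ndarray, freq_b: np.ndarray,
                            min_overlap: int = 4) -> float:
    """Best Pearson correlation of two column-frequency matrices over all
    ungapped offsets (both orientations of ``b``), requiring at least
    ``min_overlap`` overlapping columns (or the shorter motif's length)."""
    la, lb = freq_a.shape[1], freq_b.shape[1]
    min_ov = min(min_overlap, la, lb)
    best = -1.0
    for fb in (freq_b, freq_b[_RC_ROWS][:, ::-1]):
        for off in range(-(lb - min_ov), la - min_ov + 1):
            a0, a1 = max(0, off), min(la, off + lb)
            b0 = a0 - off
            xa = freq_a[:, a0:a1].ravel()
            xb = fb[:, b0:b0 + (a1 - a0)].ravel()
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            best = max(best, r)
    return best


def deduplicate_library(library: MotifLibrary,
                        similarity_cutoff: float = 0.8) -> MotifLibrary:
    """Drop near-duplicate motifs.

    Motifs are visited in descending information content and greedily grouped
    with an already-kept representative whenever the best-offset Pearson
    correlation of their frequency matrices reaches the cutoff; each group
    keeps its highest-information-content member.  The returned library
    preserves the original file order of the survivors.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    order = sorted(range(len(library)),
                   key=lambda i: -library[i].information_content)
    freqs = [_frequency_matrix(m) for m in library]
    reps: list[int] = []
    for i in order:
        if not any(best_offset_correlation(freqs[r], freqs[i]) >= similarity_cutoff
                   for r in reps):
            reps.append(i)
    keep = sorted(reps)
    return replace(library, motifs=tuple(library[i] for i in keep))
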