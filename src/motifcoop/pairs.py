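"""Active-motif detection and pair linking through attention attributions.

A motif is *active* in a sequence wherever its raw convolution (PSSM) score
reaches the motif's p=1e-4 threshold; the scores are read before batch
normalization so threshold semantics are exact.  Two active motifs at base
coordinates ``end_a`` and ``end_b`` (window-end convention) are linked by the
attribution value G^max at their pooled attention coordinates
``end // horizontal_pool``.  When a motif pair occurs at several position
combinations in one sequence, only the occurrence with the highest attribute
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .motifs import MotifLibrary
from .network import conv_scan


@dataclass(frozen=True)
class ActiveMotifHit:
    """One above-threshold motif occurrence."""

    motif_id: str
    strand: str  # '+', '-' or 'merged'
    end_bp: int
    pooled_idx: int
    score: float


@dataclass(frozen=True)
class PairAttribute:
    """One motif pair in one sequence, at its best-attributed occurrence."""

    motif_a: str
    motif_b: str
    strand_a: str
    strand_b: str
    attribute: float
    spacing_bp: int  # end-to-end distance of the two motif windows
    gap_bp: int      # bases between the motifs (edge-to-edge)
    is_self: bool


def scan_sequence(onehot: np.ndarray, library: MotifLibrary) -> np.ndarray:
    """Masked PSSM score map (L, 2*n_motifs) for one sequence: forward
    filters first, reverse complements second; incomplete windows -inf."""
    return conv_scan(onehot.astype(float), library.filter_tensor(),
                     motif_lengths=library.motif_lengths, mask_incomplete=True)


def find_active_motifs(conv_scores: np.ndarray, library: MotifLibrary,
                       pool: int = 4, merge_strands: bool = True,
                       ) -> list[ActiveMotifHit]:
    """All positions/motifs whose score reaches the motif's threshold.

    ``conv_scores`` is the masked (L, 2K) map from :func:`scan_sequence`.
    In merged mode (the default) each position reports the better of the
    forward and reverse-complement scores under a single hit; otherwise the
    strands yield separate hits against the same threshold.
    """
    k = len(library)
    thr = library.thresholds
    ids = library.ids
    fwd, rc = conv_scores[:, :k], conv_scores[:, k:]
    hits: list[ActiveMotifHit] = []
    if merge_strands:
        best = np.maximum(fwd, rc)
        pos, mot = np.nonzero(best >= thr[None, :])
        for i, j in zip(pos.tolist(), mot.tolist()):
            strand = "+" if fwd[i, j] >= rc[i, j] else "-"
            hits.append(ActiveMotifHit(ids[j], strand, i, i // pool,
                                       float(best[i, j])))
    else:
        for strand, block in (("+", fwd), ("-", rc)):
            pos, mot = np.nonzero(block >= thr[None, :])
            for i, j in zip(pos.tolist(), mot.tolist()):
                hits.append(ActiveMotifHit(ids[j], strand, i, i // pool,
                                           float(block[i, j])))
    hits.sort(key=lambda h: (h.motif_id, h.end_bp, h.strand))
    return hits


def _pair_geometry(hit_a: ActiveMotifHit, hit_b: ActiveMotifHit,
                   library: MotifLibrary) -> tuple[int, int]:
    """(end-to-end spacing, edge-to-edge gap) for two hits.

    ``end_bp`` is the 0-based coordinate of a motif's last base; the gap is
    the number of background bases strictly between the two motif instances
    (negative if they overlap).
    """
    up, down = sorted((hit_a, hit_b), key=lambda h: h.end_bp)
    spacing = down.end_bp - up.end_bp
    down_len = library[down.motif_id].length
    gap = down.end_bp - down_len - up.end_bp
    return spacing, gap


def link_pairs(hits: list[ActiveMotifHit], g_max: np.ndarray,
               library: MotifLibrary, include_self: bool = True,
               orientation_resolved: bool = False) -> list[PairAttribute]:
    """Link every pair of active motifs through G^max.

    The attribute of a hit pair at pooled coordinates (i, j) is
    ``max(G[i,j], G[j,i])`` — attention is directional but pairs are treated
    as unordered.  Per unordered motif pair only the highest-attribute
    occurrence survives; with ``orientation_resolved`` (strand-separated
    scanning) distinct strand/order combinations are kept as distinct pairs.
    Pairs of a motif with itself at two sites are flagged ``is_self`` (and
    skipped entirely when ``include_self=False``); the result is invariant
    to the input order of the hits.
    """
    m = g_max.shape[0]
    best: dict[tuple, PairAttribute] = {}
    for ha, hb in combinations(hits, 2):
        self_pair = ha.motif_id == hb.motif_id
        if self_pair and (not include_self or ha.end_bp == hb.end_bp):
            continue
        i, j = ha.pooled_idx, hb.pooled_idx
        if not (0 <= i < m and 0 <= j < m):
            raise IndexError(
                f"pooled index ({i}, {j}) outside attention grid of size {m}; "
                f"coordinate mapping is inconsistent")
        attr = float(max(g_max[i, j], g_max[j, i]))
        if orientation_resolved:
            # upstream motif first: orientation and order both matter
            up, down = sorted((ha, hb), key=lambda h: (h.end_bp, h.motif_id))
            (ma, sa), (mb, sb) = (up.motif_id, up.strand), (down.motif_id,
                                                            down.strand)
            key = (ma, sa, mb, sb)
        else:
            (ma, sa), (mb, sb) = sorted(
                [(ha.motif_id, ha.strand), (hb.motif_id, hb.strand)])
            key = (ma, mb)
        if key in best and best[key].attribute >= attr:
            continue
        spacing, gap = _pair_geometry(ha, hb, library)
        best[key] = PairAttribute(
            motif_a=ma, motif_b=mb, strand_a=sa, strand_b=sb,
            attribute=attr, spacing_bp=spacing, gap_bp=gap,
            is_self=self_pair)
    return [best[k] for k in sorted(best)]


def spacing_summary(spacings) -> tuple[float, float]:
    """Mean and sample standard deviation of spacings (sd 0 for one value)."""
    arr = np.asarray(list(spacings), dtype=float)
    if arr.size == 0:
        raise ValueError("no spacing records")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def records_frame(per_sequence: list[tuple[str, str, list[PairAttribute]]]
                  ) -> pd.DataFrame:
    """Flatten (seq_id, label, pair records) triples into a table."""
    rows = []
    for seq_id, label, recs in per_sequence:
        for r in recs:
            rows.append({
                "seq_id": seq_id, "label": label,
                "motif_a": r.motif_a, "motif_b": r.motif_b,
                "strand_a": r.strand_a, "strand_b": r.strand_b,
                "attribute": r.attribute, "spacing_bp": r.spacing_bp,
                "gap_bp": r.gap_bp, "is_self": r.is_self,
            })
    columns = ["seq_id", "label", "motif_a", "motif_b", "strand_a",
               "strand_b", "attribute", "spacing_bp", "gap_bp", "is_self"]
    return pd.DataFrame(rows, columns=columns)
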