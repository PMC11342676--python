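"""Embedded-motif benchmark simulation.

The benchmark plants a pair of motifs into random-background DNA: every
positive sequence carries one instance of *both* motifs, every negative
sequence exactly one of the two (half each).  Motif instances are drawn
column-wise from the motif's frequency matrix and embedded on a random
strand at non-overlapping positions; the rest of each 200 bp sequence is
i.i.d. background.  The generator also supports a fixed spacing range
(end-to-start gap drawn uniformly from [lo, hi]) for spacing-recovery
experiments.  Sequences receive pseudo-chromosome labels round-robin so the
standard chromosome-held-out split applies; everything is reproducible from
the seed.

``synthetic_library`` provides deterministic synthetic PSSM fixtures — two
high-information "planted" motifs plus decoys of varying information
content — so benchmarks run without any external motif database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (PSEUDO_CHROMS, DEFAULT_HELDOUT, EncodedDataset,
                   EncodedSequence, revcomp, split_by_chromosome)
from .motifs import MotifLibrary, MotifModel, UNIFORM_BACKGROUND, make_library

BASES = "ACGT"


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one embedded-motif dataset."""

    motif_a: MotifModel
    motif_b: MotifModel
    n_pos: int = 20000
    n_neg: int = 20000
    seq_len: int = 200
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    spacing_range: tuple[int, int] | None = None  # end-to-start gap, or free
    orientation_random: bool = True
    margin: int = 4  # keep instances clear of the outer bases
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.spacing_range is not None:
            lo, hi = self.spacing_range
            if lo > hi:
                raise ValueError(f"spacing range lo {lo} > hi {hi}")
            needed = (self.motif_a.length + self.motif_b.length + hi
                      + 2 * self.margin)
            if needed > self.seq_len:
                raise ValueError(
                    f"planted pair needs {needed} bp, sequence is "
                    f"{self.seq_len} bp")
        elif (self.motif_a.length + self.motif_b.length + 2 * self.margin
              > self.seq_len):
            raise ValueError("motifs do not fit in the sequence")


def sample_motif_instance(motif: MotifModel, rng: np.random.Generator,
                          min_score: float | None = None,
                          max_tries: int = 50) -> str:
    """Draw one instance string column-wise from the motif's frequencies.

    With ``min_score`` set, draws are rejected until the instance's own PSSM
    score reaches it (planted instances should be detectable occurrences);
    after ``max_tries`` rejections the consensus string is returned.
    """
    freqs = motif.pfm / motif.pfm.sum(axis=0, keepdims=True)
    cum = np.cumsum(freqs.T, axis=1)  # (L, 4)
    for _ in range(max_tries):
        u = rng.random(motif.length)
        idx = (u[:, None] <= cum).argmax(axis=1)
        if min_score is None:
            break
        if motif.pssm[idx, np.arange(motif.length)].sum() >= min_score:
            break
    else:
        return motif.consensus
    return "".join(BASES[i] for i in idx)


def _embed(seq: list[str], instance: str, start: int) -> None:
    seq[start:start + len(instance)] = list(instance)


def _place_free(rng, seq_len, margin, lengths, max_tries=100):
    """Non-overlapping uniform placements for instances of given lengths."""
    for _ in range(max_tries):
        starts = [int(rng.integers(margin, seq_len - margin - ln + 1))
                  for ln in lengths]
        spans = sorted(zip(starts, lengths))
        if all(spans[i][0] + spans[i][1] <= spans[i + 1][0]
               for i in range(len(spans) - 1)):
            return starts
    raise RuntimeError(
        f"could not place motifs of lengths {lengths} without overlap in "
        f"{max_tries} attempts")


def _background_chars(rng, n, background):
    return list("".join(BASES[c] for c in rng.choice(4, size=n, p=background)))


def build_simulation(spec: SimulationSpec,
                     heldout=DEFAULT_HELDOUT,
                     ) -> tuple[EncodedDataset, list[dict]]:
    """Generate the dataset and a ground-truth sidecar.

    The sidecar holds, per sequence, the planted motif ids, strands, start
    coordinates and (for positives) the end-to-start gap — everything an
    oracle needs to verify recovery independently of the network.
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    sequences: list[EncodedSequence] = []
    truth: list[dict] = []

    def planted_record(motif, strand, start):
        return {"motif_id": motif.id, "strand": strand, "start": start,
                "end": start + motif.length - 1}

    for i in range(spec.n_pos):
        chars = _background_chars(rng, spec.seq_len, bg)
        inst_a = sample_motif_instance(spec.motif_a, rng,
                                       min_score=spec.motif_a.threshold)
        inst_b = sample_motif_instance(spec.motif_b, rng,
                                       min_score=spec.motif_b.threshold)
        strands = (["+", "-"][rng.integers(2)] if spec.orientation_random else "+",
                   ["+", "-"][rng.integers(2)] if spec.orientation_random else "+")
        emb_a = inst_a if strands[0] == "+" else revcomp(inst_a)
        emb_b = inst_b if strands[1] == "+" else revcomp(inst_b)
        if spec.spacing_range is None:
            sa, sb = _place_free(rng, spec.seq_len, spec.margin,
                                 [len(emb_a), len(emb_b)])
            gap = None
        else:
            lo, hi = spec.spacing_range
            gap = int(rng.integers(lo, hi + 1))
            a_first = bool(rng.integers(2))
            first_len = len(emb_a) if a_first else len(emb_b)
            second_len = len(emb_b) if a_first else len(emb_a)
            total = first_len + gap + second_len
            s_first = int(rng.integers(spec.margin,
                                       spec.seq_len - spec.margin - total + 1))
            s_second = s_first + first_len + gap
            sa, sb = (s_first, s_second) if a_first else (s_second, s_first)
        _embed(chars, emb_a, sa)
        _embed(chars, emb_b, sb)
        chrom = PSEUDO_CHROMS[len(sequences) % len(PSEUDO_CHROMS)]
        sequences.append(EncodedSequence(id=f"pos_{i}", label="positive",
                                         seq="".join(chars), chrom=chrom))
        truth.append({"seq_id": f"pos_{i}", "label": "positive",
                      "planted": [planted_record(spec.motif_a, strands[0], sa),
                                  planted_record(spec.motif_b, strands[1], sb)],
                      "gap": gap if gap is not None
                      else _gap(sa, len(emb_a), sb, len(emb_b))})

    for i in range(spec.n_neg):
        chars = _background_chars(rng, spec.seq_len, bg)
        motif = spec.motif_a if i % 2 == 0 else spec.motif_b
        inst = sample_motif_instance(motif, rng, min_score=motif.threshold)
        strand = ["+", "-"][rng.integers(2)] if spec.orientation_random else "+"
        emb = inst if strand == "+" else revcomp(inst)
        start = int(rng.integers(spec.margin,
                                 spec.seq_len - spec.margin - len(emb) + 1))
        _embed(chars, emb, start)
        chrom = PSEUDO_CHROMS[len(sequences) % len(PSEUDO_CHROMS)]
        sequences.append(EncodedSequence(id=f"neg_{i}", label="negative",
                                         seq="".join(chars), chrom=chrom))
        truth.append({"seq_id": f"neg_{i}", "label": "negative",
                      "planted": [planted_record(motif, strand, start)],
                      "gap": None})

    dataset = split_by_chromosome(sequences, heldout)
    return dataset, truth


def _gap(sa, la, sb, lb):
    if sa <= sb:
        return sb - (sa + la)
    return sa - (sb + lb)


def _synthetic_pfm(rng: np.random.Generator, length: int, dominant: float,
                   total: int = 100) -> np.ndarray:
    """A PFM with one dominant base per column at the given frequency."""
    pfm = np.zeros((4, length))
    for j in range(length):
        dom = int(rng.integers(4))
        frac = dominant + rng.uniform(-0.05, 0.05)
        frac = min(max(frac, 0.3), 0.95)
        rest = (1.0 - frac) * rng.dirichlet(np.ones(3))
        col = np.insert(rest, dom, frac)
        pfm[:, j] = np.rint(col * total)
        pfm[dom, j] += total - pfm[:, j].sum()
    return pfm


def synthetic_library(n_motifs: int = 20, seed: int = 101,
                      n_strong: int = 2,
                      strong_dominant: float = 0.85,
                      strong_length_range: tuple[int, int] = (11, 14),
                      decoy_dominant: tuple[float, float] = (0.5, 0.75),
                      length_range: tuple[int, int] = (8, 14),
                      ) -> MotifLibrary:
    """Deterministic synthetic motif fixtures.

    The first ``n_strong`` motifs are high-information (suitable for
    planting) and drawn at 11-14 bp — the size and information range of the
    real TF motifs typically used in embedded-motif benchmarks; the rest are
    decoys of lower, varied information content at 8-14 bp.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_motifs):
        if k < n_strong:
            length = int(rng.integers(strong_length_range[0],
                                      strong_length_range[1] + 1))
            dom = strong_dominant
            name = f"planted_{k}"
        else:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            dom = float(rng.uniform(*decoy_dominant))
            name = f"decoy_{k - n_strong}"
        records.append((f"SYN{k:03d}", name, _synthetic_pfm(rng, length, dom)))
    return make_library(records)


def null_simulation(n_pos: int, n_neg: int, seq_len: int = 200,
                    background: np.ndarray | None = None,
                    seed: int = 0, heldout=DEFAULT_HELDOUT) -> EncodedDataset:
    """Signal-free control: both classes are pure background sequences.

    Labels carry no information, so a correctly calibrated pipeline should
    classify at chance and report no significant pairs.
    """
    rng = np.random.default_rng(seed)
    bg = np.asarray(background if background is not None
                    else UNIFORM_BACKGROUND, dtype=float)
    sequences = []
    for i in range(n_pos + n_neg):
        label = "positive" if i < n_pos else "negative"
        chrom = PSEUDO_CHROMS[i % len(PSEUDO_CHROMS)]
        sequences.append(EncodedSequence(
            id=f"{label[:3]}_{i}", label=label,
            seq="".join(_background_chars(rng, seq_len, bg)), chrom=chrom))
    return split_by_chromosome(sequences, heldout)


@dataclass
class BenchmarkReport:
    """Summary of one benchmark run on a simulated dataset."""

    planted_pair: tuple[str, str]
    test_auc: float
    planted_rank: int | None  # 1-based rank among tested pairs, None if untested
    planted_p_adj: float | None
    n_pairs_tested: int
    n_pairs_significant: int
    spacing_mean: float | None
    spacing_sd: float | None
    gap_mean: float | None
    gap_sd: float | None
    results: "object" = None  # pandas DataFrame of all tested pairs


def run_benchmark(spec: SimulationSpec, library: MotifLibrary,
                  model_config=None, epochs: int | None = None,
                  ig_steps: int = 100, outdir=None) -> BenchmarkReport:
    """Full pipeline on a simulated dataset; report the planted pair's fate."""
    from .network import ModelConfig
    from .pipeline import run

    if model_config is None:
        model_config = ModelConfig(n_motifs=len(library), seed=spec.seed)
    dataset, _ = build_simulation(spec)
    result = run(dataset, library, model_config, ig_steps=ig_steps,
                 outdir=outdir, epochs=epochs)
    pair = tuple(sorted((spec.motif_a.id, spec.motif_b.id)))
    res = result.results
    rank = p_adj = sp_mean = sp_sd = gp_mean = gp_sd = None
    if not res.empty:
        match = res.index[(res["motif_a"] == pair[0])
                          & (res["motif_b"] == pair[1])]
        if len(match):
            row = res.loc[match[0]]
            rank = int(match[0]) + 1
            p_adj = float(row["p_adj"])
            sp_mean, sp_sd = float(row["spacing_mean"]), float(row["spacing_sd"])
            gp_mean, gp_sd = float(row["gap_mean"]), float(row["gap_sd"])
    return BenchmarkReport(
        planted_pair=pair, test_auc=result.test_auc,
        planted_rank=rank, planted_p_adj=p_adj,
        n_pairs_tested=len(res),
        n_pairs_significant=int(res["significant"].sum()) if not res.empty else 0,
        spacing_mean=sp_mean, spacing_sd=sp_sd,
        gap_mean=gp_mean, gap_sd=gp_sd, results=res)


def scan_back_validate(dataset: EncodedDataset, truth: list[dict],
                       library: MotifLibrary, pair_ids: tuple[str, str],
                       ) -> dict:
    """Direct PSSM-scan oracle, independent of the network.

    Returns the fraction of positives with both planted motifs detectable at
    their thresholds and the fraction of negatives where both score above
    threshold anywhere (spurious co-occurrence included).
    """
    from .pairs import find_active_motifs, scan_sequence

    pos_both = neg_both = n_pos = n_neg = 0
    for seq, rec in zip(dataset.sequences, truth):
        hits = find_active_motifs(scan_sequence(seq.onehot, library), library)
        found = {h.motif_id for h in hits}
        both = pair_ids[0] in found and pair_ids[1] in found
        if rec["label"] == "positive":
            n_pos += 1
            pos_both += both
        else:
            n_neg += 1
            neg_both += both
    return {"pos_both_fraction": pos_both / max(n_pos, 1),
            "neg_both_fraction": neg_both / max(n_neg, 1)}
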