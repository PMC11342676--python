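"""End-to-end orchestration: train, attribute, link, test, write outputs.

A run takes an :class:`~motifcoop.data.EncodedDataset` plus a motif library,
trains the classifier on the chromosome-based train split, computes
integrated-gradients attention attributions for confidently-predicted
sequences, links active motif pairs per sequence, and tests each pair's
attributes in positive vs negative sequences.  Attribution is skipped for
sequences that the 0.7/0.3 prediction filter would discard anyway and for
sequences without at least two distinct active motifs — both sets contribute
no record, so results are identical and interpretation time drops.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .attribution import integrated_gradients_attention
from .data import EncodedDataset
from .motifs import MotifLibrary
from .network import (AttentionClassifier, ModelConfig, compute_feature_maps,
                      conv_scan, vertical_pool)
from .pairs import find_active_motifs, link_pairs, records_frame

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """In-memory products of one pipeline run."""

    model: AttentionClassifier
    scores: dict[str, float]
    records: pd.DataFrame
    results: pd.DataFrame
    untested: pd.DataFrame
    test_auc: float
    counts: dict[str, int] = field(default_factory=dict)
    attributions: dict[str, np.ndarray] = field(default_factory=dict)


def _feature_maps_and_hits(dataset: EncodedDataset, library: MotifLibrary,
                           config: ModelConfig, chunk: int = 256):
    """One chunked pass over the frozen conv stage.

    Produces the classifier input maps and, from the same raw scores (with
    incomplete windows masked), the per-sequence active-motif hits.
    """
    filters = library.filter_tensor()
    lengths = library.motif_lengths
    n = len(dataset)
    maps = np.empty((n, config.input_len, config.n_features))
    hits = []
    merge = not config.compute_rc
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        onehots = dataset.onehot_array(range(c0, c1)).astype(float)
        raw = conv_scan(onehots, filters, motif_lengths=lengths,
                        mask_incomplete=False)
        maps[c0:c1] = vertical_pool(raw, config.compute_rc)
        masked = raw.copy()
        for k, lk in enumerate(np.concatenate([lengths, lengths])):
            masked[:, : int(lk) - 1, k] = -np.inf
        for i in range(c1 - c0):
            hits.append(find_active_motifs(masked[i], library,
                                           pool=config.horizontal_pool,
                                           merge_strands=merge))
    return maps, hits


def run(dataset: EncodedDataset, library: MotifLibrary, config: ModelConfig,
        ig_steps: int = 100, outdir: str | Path | None = None,
        epochs: int | None = None) -> RunResult:
    """Train on the dataset and infer significant motif pairs."""
    config.validate()
    counts: dict[str, int] = {"sequences": len(dataset)}
    logger.info("computing feature maps and active motifs for %d sequences",
                len(dataset))
    maps, hits = _feature_maps_and_hits(dataset, library, config)
    labels = dataset.labels()

    model = AttentionClassifier(library, config)
    logger.info("training for %d epochs on %d sequences",
                epochs or config.epochs, len(dataset.train_idx))
    model.fit(maps, labels, dataset.train_idx, dataset.test_idx,
              epochs=epochs,
              log_fn=lambda row: logger.info(
                  "epoch %d: loss %.4f, test AUC %.4f",
                  row["epoch"], row["train_loss"], row["test_auc"]))

    scores_arr = model.predict(maps)
    ids = dataset.ids()
    scores = dict(zip(ids, scores_arr.tolist()))

    confident = np.where(labels == 1, scores_arr >= stats.POS_SCORE_MIN,
                         scores_arr <= stats.NEG_SCORE_MAX)
    counts["confident"] = int(confident.sum())
    pairable = np.array([len({h.motif_id for h in hs}) >= 2 for hs in hits])
    cand = np.nonzero(confident & pairable)[0]
    counts["attributed"] = len(cand)
    logger.info("%d/%d sequences pass the prediction filter; "
                "%d carry >=2 active motifs and are attributed",
                counts["confident"], len(dataset), len(cand))

    attributions = integrated_gradients_attention(
        model, maps[cand], steps=ig_steps, seq_ids=[ids[i] for i in cand])

    per_sequence = []
    for i, attr in zip(cand, attributions):
        recs = link_pairs(hits[i], attr.g_max, library,
                          orientation_resolved=config.compute_rc)
        per_sequence.append((ids[i], dataset.sequences[i].label, recs))
    records = records_frame(per_sequence)
    counts["pair_records"] = len(records)

    results, untested = stats.test_pairs(records, scores, prefiltered=True)
    counts["pairs_tested"] = len(results)
    counts["pairs_significant"] = int(results["significant"].sum()) \
        if not results.empty else 0
    logger.info("tested %d pairs (%d untested); %d significant",
                counts["pairs_tested"], len(untested),
                counts["pairs_significant"])

    result = RunResult(model=model, scores=scores, records=records,
                       results=results, untested=untested,
                       test_auc=model.test_auc, counts=counts,
                       attributions={a.seq_id: a.g_max for a in attributions})
    if outdir is not None:
        write_outputs(result, library, config, Path(outdir))
    return result


def write_outputs(result: RunResult, library: MotifLibrary,
                  config: ModelConfig, outdir: Path) -> Path:
    """Write the standard run directory: CSVs, HTML report, checkpoint."""
    from .report import render_report

    outdir.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(outdir / "results.csv", index=False)
    result.records.to_csv(outdir / "pair_attributes.csv", index=False)
    result.untested.to_csv(outdir / "untested_pairs.csv", index=False)
    pd.DataFrame({"seq_id": list(result.scores),
                  "score": list(result.scores.values())}
                 ).to_csv(outdir / "prediction_scores.csv", index=False)
    pd.DataFrame(result.model.history).to_csv(outdir / "training_history.csv",
                                              index=False)
    library.manifest().to_csv(outdir / "library_manifest.csv", index=False)
    result.model.save(outdir / "checkpoint.npz")
    if result.attributions:
        np.savez_compressed(outdir / "attention_attributes.npz",
                            **result.attributions)
    cfg = {**vars(config), "fc_units": list(config.fc_units)}
    (outdir / "config.json").write_text(json.dumps(
        {"model": cfg, "counts": result.counts,
         "test_auc": result.test_auc}, indent=2))
    (outdir / "report.html").write_text(
        render_report(result.results, result.counts))
    return outdir
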