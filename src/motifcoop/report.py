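"""HTML report of significant motif pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import SIGNIFICANCE_ALPHA, rank_significant

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Motif pair cooperativity report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; text-align: right; }}
th {{ background: #eee; cursor: pointer; }}
td:first-child, td:nth-child(2) {{ text-align: left; }}
</style>
</head>
<body>
<h1>Significant motif pairs</h1>
<p>{summary}</p>
{table}
<h2>Run counts</h2>
<ul>{counts}</ul>
</body>
</html>
"""


def _fmt_p(p: float) -> str:
    # an exact zero only means underflow of the normal-tail computation
    return "&lt;1e-300" if p == 0 else f"{p:.3g}"


def render_report(results: pd.DataFrame, counts: dict | None = None,
                  alpha: float = SIGNIFICANCE_ALPHA) -> str:
    """Render the significant-pair table (sorted by adjusted p) as HTML.

    Columns mirror the CSV: adjusted p (and its -log10), mean attention
    attribute in positive vs negative sequences, and the spacing summary.
    """
    counts_html = "".join(f"<li>{k}: {v}</li>"
                          for k, v in (counts or {}).items())
    sig = rank_significant(results, alpha)
    if sig.empty:
        return _PAGE.format(
            summary=f"No motif pair reached adjusted p &lt; {alpha:g}.",
            table="", counts=counts_html)
    view = pd.DataFrame({
        "motif A": sig["motif_a"],
        "motif B": sig["motif_b"],
        "adjusted p": sig["p_adj"].map(_fmt_p),
        "-log10(p)": (-np.log10(np.maximum(sig["p_adj"], 1e-300))).round(2),
        "mean attr (pos)": sig["mean_attr_pos"].map(lambda v: f"{v:.4g}"),
        "mean attr (neg)": sig["mean_attr_neg"].map(lambda v: f"{v:.4g}"),
        "n pos": sig["n_pos"], "n neg": sig["n_neg"],
        "spacing mean": sig["spacing_mean"].round(1),
        "spacing sd": sig["spacing_sd"].round(1),
    })
    table = view.to_html(index=False, escape=False)
    return _PAGE.format(
        summary=f"{len(sig)} motif pair(s) with adjusted p &lt; {alpha:g}, "
                "sorted by p-value.",
        table=table, counts=counts_html)
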