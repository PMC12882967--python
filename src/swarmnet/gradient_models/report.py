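"""Significance tables for fitted models.

Reproduces the layout of the two results tables: per-metric coefficient
tables with 95% CIs for the GLMMs, and per-smooth e.d.f. / p-value rows
for the GAMMs.  A fixed effect is flagged significant when p ≤ 0.05
(boundary inclusive) or, equivalently for the GLMMs, when the Wald CI
excludes zero.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .gamm import GammFit
from .glmm import GlmmFit

P_THRESHOLD = 0.05


def glmm_report(fits: Mapping[str, GlmmFit] | Sequence[GlmmFit]) -> pd.DataFrame:
    """Coefficient table across metric GLMMs with significance flags."""
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    rows = []
    for fit in fits:
        for _, r in fit.params.iterrows():
            ci_excl_zero = (r["ci_lo"] > 0) or (r["ci_hi"] < 0)
            rows.append(
                {
                    "response": fit.spec.response,
                    "term": r["term"],
                    "estimate": r["estimate"],
                    "ci_lo": r["ci_lo"],
                    "ci_hi": r["ci_hi"],
                    "p": r["p"],
                    "significant": bool(r["p"] <= P_THRESHOLD and ci_excl_zero),
                }
            )
    return pd.DataFrame(rows)


def gamm_report(fits: Mapping[str, GammFit] | Sequence[GammFit]) -> pd.DataFrame:
    """e.d.f. / p-value table across dissimilarity GAMMs."""
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    rows = []
    for fit in fits:
        for name in fit.spec.smooths:
            rows.append(
                {
                    "response": fit.spec.response,
                    "term": name,
                    "edf": fit.edf[name],
                    "p": fit.pvalues[name],
                    "significant": bool(fit.pvalues[name] <= P_THRESHOLD),
                }
            )
    return pd.DataFrame(rows)


def significance_report(fits) -> pd.DataFrame:
    """Dispatch on fit type; accepts a mapping/sequence of GLMM or GAMM fits."""
    items = list(fits.values()) if isinstance(fits, Mapping) else list(fits)
    if not items:
        raise ValueError("no fits to report")
    if isinstance(items[0], GlmmFit):
        return glmm_report(items)
    return gamm_report(items)


def render_text_table(report: pd.DataFrame, *, title: str = "") -> str:
    """Plain-text rendering of a report table (bold-free Table 1/2 mirror)."""
    lines = []
    if title:
        lines += [title, "=" * len(title)]
    fmt = {c: "{:.3f}".format for c in report.columns if report[c].dtype.kind == "f"}
    lines.append(report.to_string(index=False, formatters=fmt))
    return "\n".join(lines) + "\n"
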