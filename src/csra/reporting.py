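"""Cohort-level summaries: SI histograms, resistance fractions, oncoplot table.

Canonical outputs are TSV/JSON tables; figures, when requested, are rendered
from those tables and never the reverse.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, JoinError
from .plates import RESISTANT, SENSITIVE, SENSITIVITY_THRESHOLD

SI_MAX = 600.0


def resistance_fractions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-drug fraction of resistant calls among evaluable specimens."""
    rows = []
    for drug, grp in calls.groupby("drug", sort=False):
        evaluable = grp[grp["call"].isin([SENSITIVE, RESISTANT])]
        n = len(evaluable)
        rows.append(
            {
                "drug": drug,
                "n_evaluable": n,
                "n_resistant": int((evaluable["call"] == RESISTANT).sum()),
                "fraction_resistant": float((evaluable["call"] == RESISTANT).mean())
                if n
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def si_histogram(
    results: pd.DataFrame,
    bin_width: float = 50.0,
    si_column: str = "si_clamped",
) -> pd.DataFrame:
    """Bin SI values per histotype and drug over [0, 600].

    Bins are right-open except the last, which includes 600 so that no score
    is dropped; the default width of 50 makes the sensitivity threshold at
    250 a bin boundary.  ``results`` needs columns drug, histotype and the
    SI column.  Returns long form: drug, histotype, bin_left, bin_right,
    count, side (sensitive/resistant by the bin's position vs the threshold).
    """
    if bin_width <= 0:
        raise ConfigError(f"bin width must be positive, got {bin_width}")
    if results.empty:
        raise ConfigError("no SI results to bin")
    edges = np.arange(0.0, SI_MAX + bin_width, bin_width)
    if edges[-1] < SI_MAX:
        edges = np.append(edges, SI_MAX)
    rows = []
    for (drug, histotype), grp in results.groupby(["drug", "histotype"], sort=False):
        counts, _ = np.histogram(grp[si_column].to_numpy(dtype=float), bins=edges)
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "drug": drug,
                    "histotype": histotype,
                    "bin_left": left,
                    "bin_right": right,
                    "count": int(count),
                    "side": "sensitive" if right <= SENSITIVITY_THRESHOLD else "resistant",
                }
            )
    return pd.DataFrame(rows)


def oncoplot_matrix(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    drugs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Specimen x (genes..., per-drug call) co-occurrence table.

    Rows are specimens sorted by histotype (UPS before SS) with mutated
    specimens first within each histotype; gene columns are 0/1 and drug
    columns carry R/S/NA.  All three inputs must share a specimen universe.
    """
    spec_matrix = set(matrix.index)
    spec_ann = set(annotations["specimen_id"])
    if spec_matrix != spec_ann:
        raise JoinError(
            "mutation matrix and annotations cover different specimens: "
            f"{sorted(spec_matrix ^ spec_ann)[:5]}..."
        )
    unknown = set(calls["specimen_id"]) - spec_ann
    if unknown:
        raise JoinError(f"calls reference unknown specimens: {sorted(unknown)[:5]}")
    if drugs is None:
        drugs = list(dict.fromkeys(calls["drug"]))

    out = matrix.copy()
    histotype = annotations.set_index("specimen_id")["histotype"]
    out.insert(0, "histotype", histotype.reindex(out.index))
    short = {SENSITIVE: "S", RESISTANT: "R"}
    for drug in drugs:
        col = (
            calls[calls["drug"] == drug]
            .set_index("specimen_id")["call"]
            .map(lambda c: short.get(c, "NA"))
        )
        out[drug] = col.reindex(out.index).fillna("NA")
    n_mut = matrix.sum(axis=1) if matrix.shape[1] else pd.Series(0, index=matrix.index)
    out["_mut"] = (n_mut > 0).astype(int)
    out["_h"] = out["histotype"].map({"UPS": 0, "SS": 1}).fillna(2)
    out = out.sort_values(["_h", "_mut"], ascending=[True, False], kind="stable")
    return out.drop(columns=["_mut", "_h"])


def write_oncoplot(oncoplot: pd.DataFrame, path) -> None:
    oncoplot.to_csv(path, sep="\t", index_label="specimen_id")


def read_oncoplot(path) -> pd.DataFrame:
    """Inverse of :func:`write_oncoplot` (round-trips matrix and calls)."""
    df = pd.read_csv(
        path, sep="\t", index_col="specimen_id", dtype=str, keep_default_na=False
    )
    for col in df.columns:
        if col != "histotype" and set(df[col].unique()) <= {"0", "1"}:
            df[col] = df[col].astype(int)
    return df


def plot_si_histogram(hist: pd.DataFrame, path, drug: str | None = None) -> None:
    """Render the binned SI distribution to an image file (optional artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = hist if drug is None else hist[hist["drug"] == drug]
    drugs = list(dict.fromkeys(data["drug"]))
    fig, axes = plt.subplots(1, len(drugs), figsize=(4 * len(drugs), 3), squeeze=False)
    for ax, d in zip(axes[0], drugs):
        sub = data[data["drug"] == d].groupby(["bin_left", "side"], as_index=False)["count"].sum()
        colors = sub["side"].map({"sensitive": "tab:green", "resistant": "tab:red"})
        ax.bar(sub["bin_left"], sub["count"], width=40, color=colors, align="edge")
        ax.axvline(SENSITIVITY_THRESHOLD, ls="--", c="k", lw=0.8)
        ax.set_title(d)
        ax.set_xlabel("SI")
    axes[0][0].set_ylabel("cultures")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
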