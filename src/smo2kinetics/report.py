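"""Group summary tables and fitted-round figures.

Tables mirror the field's reporting style: one row per (round, leg,
training) cell, ``mean ± SD`` per metric (sample SD, omitted at n = 1),
rounded to metric-appropriate precision (times 1 dp, rates 2 dp, heart
rates integer), with significance superscripts attached from paired
cell contrasts at p < 0.05.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EXERCISE_METRICS",
    "RECOVERY_METRICS",
    "PUNCH_METRICS",
    "summarise_cells",
    "paired_cell_contrasts",
    "build_tables",
    "format_table",
    "plot_fitted_round",
]

# metric -> decimal places
EXERCISE_METRICS = {
    "TD": 1, "HRS": 0, "FDR": 2, "FDReN": 2,
    "DD": 1, "MAD_FD": 1, "HRE": 0, "MAD_Eq": 1,
}
RECOVERY_METRICS = {
    "RD": 1, "HRSF": 0, "FRR": 2, "FRD": 1,
    "MAD_FR": 1, "HREF": 0, "MAD_SR": 1,
}
PUNCH_METRICS = {"punches_td": 0, "punches_fd": 0, "punches_rt": 0}

_LEGS = ("lead", "rear")
_TRAININGS = ("bag", "pad", "spar")

# superscript scheme: leg / training / round comparison families
_TRAINING_LABELS = {
    ("lead", "spar", "bag"): "b",
    ("lead", "spar", "pad"): "c",
    ("lead", "pad", "bag"): "d",
    ("rear", "spar", "bag"): "e",
    ("rear", "spar", "pad"): "f",
    ("rear", "pad", "bag"): "g",
}


def summarise_cells(fits: pd.DataFrame, metrics: dict[str, int]) -> pd.DataFrame:
    """Per-cell mean, sample SD and n for each metric (long format)."""
    rows = []
    for (rnd, leg, training), grp in fits.groupby(["round", "leg", "training"]):
        for metric in metrics:
            vals = grp[metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "round": rnd,
                    "leg": leg,
                    "training": training,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "n": int(vals.size),
                }
            )
    if not rows:
        raise ValueError("no fits to summarise")
    return pd.DataFrame(rows)


def _paired(grp_a: pd.DataFrame, grp_b: pd.DataFrame, metric: str):
    """Paired t over athletes common to both cells; None when underpowered."""
    a = grp_a.set_index("athlete")[metric].dropna()
    b = grp_b.set_index("athlete")[metric].dropna()
    common = a.index.intersection(b.index)
    if len(common) < 2:
        return None
    da, db = a.loc[common], b.loc[common]
    if np.allclose(da, db):
        return 0.0, 1.0, 0.0
    t, p = sps.ttest_rel(da, db)
    return float(t), float(p), float((da - db).mean())


def paired_cell_contrasts(fits: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Cell-wise follow-up contrasts for one outcome, three families:

    * leg (label ``a``): rear vs lead within each (training, round);
    * training (``b``-``g``): modality pairs within each (leg, round);
    * round (``h``-``l``): each earlier round vs rounds 2-6 within each
      (training, leg), the marker attached to the earlier round's cell.

    Each contrast is a paired t test across athletes (the cell pair's own
    error term rather than a pooled one).
    """
    rows = []
    cells = {k: g for k, g in fits.groupby(["round", "leg", "training"])}
    rounds = sorted(fits["round"].unique())

    for rnd in rounds:
        for training in _TRAININGS:
            ka, kb = (rnd, "lead", training), (rnd, "rear", training)
            if ka in cells and kb in cells:
                res = _paired(cells[ka], cells[kb], metric)
                if res:
                    rows.append(
                        dict(metric=metric, family="leg", label="a",
                             round=rnd, leg="lead", training=training,
                             t=res[0], p=res[1], mean_diff=res[2])
                    )
    for rnd in rounds:
        for (leg, m1, m2), label in _TRAINING_LABELS.items():
            ka, kb = (rnd, leg, m1), (rnd, leg, m2)
            if ka in cells and kb in cells:
                res = _paired(cells[ka], cells[kb], metric)
                if res:
                    rows.append(
                        dict(metric=metric, family="training", label=label,
                             round=rnd, leg=leg, training=m1,
                             t=res[0], p=res[1], mean_diff=res[2])
                    )
    for training in _TRAININGS:
        for leg in _LEGS:
            for i, r1 in enumerate(rounds):
                for r2 in rounds[i + 1:]:
                    ka, kb = (r1, leg, training), (r2, leg, training)
                    if ka in cells and kb in cells and r2 >= 2:
                        res = _paired(cells[ka], cells[kb], metric)
                        if res:
                            rows.append(
                                dict(metric=metric, family="round",
                                     label=chr(ord("h") + int(r2) - 2),
                                     round=r1, leg=leg, training=training,
                                     t=res[0], p=res[1], mean_diff=res[2])
                            )
    return pd.DataFrame(rows)


def _format_cell(mean: float, sd: float, dp: int, marks: str) -> str:
    m = f"{mean:.{dp}f}"
    if np.isfinite(sd):
        m += f" ± {sd:.{dp}f}"
    if marks:
        m += f" {marks}"
    return m


def build_tables(
    fits: pd.DataFrame, contrasts: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exercise- and recovery-shaped summary tables from a fits frame.

    ``fits`` carries one row per (athlete, training, leg, kind, round) with
    the fitted metrics as columns; ``contrasts`` (optional) is a
    concatenation of :func:`paired_cell_contrasts` frames whose p < 0.05
    entries become superscript markers.  Rows are ordered round-major.
    """
    if fits.empty:
        raise ValueError("empty fits")
    tables = []
    for kind, metrics in (("round", {**EXERCISE_METRICS, **PUNCH_METRICS}),
                          ("rest", RECOVERY_METRICS)):
        sub = fits[fits["kind"] == kind]
        if sub.empty:
            tables.append(pd.DataFrame())
            continue
        present = {m: dp for m, dp in metrics.items() if m in sub.columns}
        summary = summarise_cells(sub, present)
        sig = {}
        if contrasts is not None and not contrasts.empty:
            hits = contrasts[(contrasts["p"] < 0.05)]
            for _, row in hits.iterrows():
                key = (row["metric"], row["round"], row["leg"], row["training"])
                sig.setdefault(key, []).append(row["label"])
        records = {}
        for _, row in summary.iterrows():
            key = (row["round"], row["leg"], row["training"])
            marks = "".join(
                sorted(sig.get((row["metric"], *key), []))
            )
            records.setdefault(key, {})[row["metric"]] = _format_cell(
                row["mean"], row["sd"], present[row["metric"]], marks
            )
        index = [
            k for k in sorted(records, key=lambda k: (k[0], k[1], k[2]))
        ]
        table = pd.DataFrame(
            [records[k] for k in index],
            index=pd.MultiIndex.from_tuples(index, names=["round", "leg", "training"]),
            columns=list(present),
        )
        tables.append(table)
    return tables[0], tables[1]


def format_table(table: pd.DataFrame, title: str) -> str:
    buf = StringIO()
    buf.write(f"{title}\n")
    buf.write(table.to_string())
    buf.write("\n")
    return buf.getvalue()


def plot_fitted_round(window, fit, path=None):
    """Overlay the three fitted segments on one window's SmO2 trace."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(window.local_time, window.smo2, lw=0.8, color="0.4", label="SmO2")
    for seg in fit.segments:
        t0, t1 = seg.span
        tt = np.linspace(t0, t1, 20)
        ax.plot(tt, seg.predict(tt), lw=2.0)
    ax.set_xlabel("time in window (s)")
    ax.set_ylabel("SmO2 (%)")
    ax.set_title(f"{window.kind} {window.index} ({window.leg} leg)")
    ax.legend(loc="best")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
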