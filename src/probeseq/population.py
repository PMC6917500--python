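"""Treatment-response classification of subpopulations.

For each cluster i the frequency in a treatment arm j is compared with the
vehicle (e.g. DMSO) arm through the ratio of total-population fractions
d_(j,i),total / d_(vehicle,i),total, where d_(j,i),total = d_j,i × d_i,total.
The two ratios — control compound over vehicle (r_b) and probe over
vehicle (r_a) — place the cluster into one of five categories with the
thresholds 0.8 / 1.2 on each ratio and 0.15 on their separation:

    commonly_resistant       0.8 < r_b < 1.2  and 0.8 < r_a < 1.2
    commonly_emerging        r_b >= 1.2 and r_a >= 1.2
    commonly_depleted        r_b <= 0.8 and r_a <= 0.8 and |r_b - r_a| < 0.15
    differentially_depleted  (r_b < 0.8 or r_a < 0.8) and |r_b - r_a| > 0.15
    differentially_emerging  r_b > 1.2 or r_a > 1.2

The published rules overlap and leave gaps; they are applied in the fixed
precedence above, with anything unmatched reported as ``unclassified``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["classify_shift", "origin_cluster_fractions", "population_shift_table", "CATEGORIES"]

CATEGORIES = (
    "commonly_resistant",
    "commonly_emerging",
    "commonly_depleted",
    "differentially_emerging",
    "differentially_depleted",
    "unclassified",
)


def classify_shift(
    r_b: float, r_a: float, low: float = 0.8, high: float = 1.2, diff: float = 0.15
) -> str:
    """Category of one cluster from its (control/vehicle, probe/vehicle) ratios."""
    if not (np.isfinite(r_b) and np.isfinite(r_a)):
        return "unclassified"
    if low < r_b < high and low < r_a < high:
        return "commonly_resistant"
    if r_b >= high and r_a >= high:
        return "commonly_emerging"
    if r_b <= low and r_a <= low and abs(r_b - r_a) < diff:
        return "commonly_depleted"
    if (r_b < low or r_a < low) and abs(r_b - r_a) > diff:
        return "differentially_depleted"
    if r_b > high or r_a > high:
        return "differentially_emerging"
    return "unclassified"


def origin_cluster_fractions(
    labels,
    origins,
    vehicle_origin: str,
    control_origin: str | None = None,
    probe_origin: str | None = None,
    mode: str = "conditional",
) -> pd.DataFrame:
    """Per-cluster origin fractions and treatment/vehicle frequency ratios.

    Two ratio conventions are supported:

    * ``"conditional"`` (default) — ratios of per-origin conditional cluster
      frequencies P(cluster i | origin j) = N_ji / N_j, robust to unequal
      arm sizes;
    * ``"literal"`` — ratios of total-population fractions
      d_(j,i),total / d_(vehicle,i),total, which reduce to N_ji / N_vi.

    The two agree exactly when the arms have equal cell totals.  Clusters
    with no vehicle cell are flagged (``vehicle_defined=False``) and their
    ratios set to NaN (or +inf when the arm count is positive in literal
    accounting of an empty vehicle — avoided here for auditability).
    """
    if mode not in ("conditional", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    origins = np.asarray(origins)
    origin_names = list(pd.unique(origins))
    if vehicle_origin not in origin_names:
        raise ValueError(f"vehicle origin {vehicle_origin!r} absent from data")
    others = [o for o in origin_names if o != vehicle_origin]
    if control_origin is None or probe_origin is None:
        if len(others) != 2:
            raise ValueError("specify control_origin and probe_origin explicitly")
        control_origin, probe_origin = others

    tab = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(origins, name="origin"))
    for o in (vehicle_origin, control_origin, probe_origin):
        if o not in tab.columns:
            tab[o] = 0
    n_total = tab.to_numpy().sum()
    n_per_origin = tab.sum(axis=0)
    cluster_size = tab.sum(axis=1)

    rows = []
    for cl in tab.index:
        n_v = tab.at[cl, vehicle_origin]
        n_b = tab.at[cl, control_origin]
        n_a = tab.at[cl, probe_origin]
        d_i_total = cluster_size[cl] / n_total
        d_ji = {o: tab.at[cl, o] / cluster_size[cl] for o in tab.columns}
        defined = n_v > 0
        if not defined:
            r_b = r_a = np.nan
        elif mode == "literal":
            r_b, r_a = n_b / n_v, n_a / n_v
        else:
            r_b = (n_b / n_per_origin[control_origin]) / (n_v / n_per_origin[vehicle_origin])
            r_a = (n_a / n_per_origin[probe_origin]) / (n_v / n_per_origin[vehicle_origin])
        rows.append(
            {
                "cluster": cl,
                "n_vehicle": int(n_v),
                "n_control": int(n_b),
                "n_probe": int(n_a),
                "d_i_total": d_i_total,
                **{f"d_{o}": d_ji[o] for o in tab.columns},
                **{f"d_total_{o}": d_ji[o] * d_i_total for o in tab.columns},
                "ratio_control": r_b,
                "ratio_probe": r_a,
                "vehicle_defined": bool(defined),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def population_shift_table(
    labels,
    origins,
    vehicle_origin: str,
    control_origin: str | None = None,
    probe_origin: str | None = None,
    mode: str = "conditional",
    low: float = 0.8,
    high: float = 1.2,
    diff: float = 0.15,
) -> pd.DataFrame:
    """Origin/cluster fractions plus the shift category per cluster."""
    df = origin_cluster_fractions(
        labels, origins, vehicle_origin, control_origin, probe_origin, mode=mode
    )
    df["category"] = [
        classify_shift(rb, ra, low=low, high=high, diff=diff) if ok else "unclassified"
        for rb, ra, ok in zip(df["ratio_control"], df["ratio_probe"], df["vehicle_defined"])
    ]
    return df
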