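"""Assigned-versus-closest facility reassignment scenarios and reporting.

Workers currently travel to an administratively assigned health center
(CSB) or supply point (PA).  The scenario analysis compares that against
reassignment to the closest facility of the same kind, where "closest"
means the facility minimising the fokontany's mean travel time (the
workers of a fokontany are reassigned as a unit).  A per-cell-minimum
variant — mean over habitable cells of the minimum across facilities —
is available behind ``method="cell_min"``.

Facilities with no workers assigned anywhere are not suitable reassignment
targets.  Fokontany whose commune has no supply point are excluded from
the PA analysis with an explicit reason, and all exclusions are kept as
rows rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodata import Grid, VectorLayer

__all__ = [
    "closest_facility",
    "build_scenarios",
    "bin_travel_times",
    "district_summary",
    "render_report",
    "BIN_LABELS",
]

BIN_LABELS = ["le_2h", "2_to_4h", "gt_4h"]
_BIN_EDGES_MIN = [0.0, 120.0, 240.0, float("inf")]


def closest_facility(
    mean_times: pd.DataFrame,
    eligible: set[str],
) -> pd.DataFrame:
    """Per-fokontany argmin of mean travel time over eligible facilities.

    ``mean_times`` is the long table from :func:`~chw_access.travel_time.
    facility_fields` (fokontany_id, facility_id, mean_minutes).  Ties break
    by lexicographic facility id.  Returns columns fokontany_id, closest_id,
    closest_minutes.
    """
    if not eligible:
        raise ValueError("no eligible facility")
    sub = mean_times[mean_times["facility_id"].isin(eligible)].copy()
    sub = sub.sort_values(["fokontany_id", "mean_minutes", "facility_id"])
    best = sub.groupby("fokontany_id", as_index=False).first()
    return best.rename(columns={"facility_id": "closest_id", "mean_minutes": "closest_minutes"})[
        ["fokontany_id", "closest_id", "closest_minutes"]
    ]


def _cell_min_closest(
    fields: dict[str, Grid],
    eligible: set[str],
    mask: Grid,
    cell_indices: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-cell-minimum variant: mean over habitable cells of the pointwise
    minimum field; closest_id is the facility winning the most cells."""
    ids = sorted(eligible)
    stack = np.stack([np.asarray(fields[i].values, dtype=float).ravel() for i in ids])
    mv = np.asarray(mask.values, dtype=bool).ravel()
    records = []
    for pid, cells in cell_indices.items():
        hab = cells[mv[cells]]
        use = hab if hab.size else cells
        sub = stack[:, use]
        per_cell_min = sub.min(axis=0)
        finite = np.isfinite(per_cell_min)
        mean = float(per_cell_min[finite].mean()) if finite.any() else float("inf")
        winner = ids[int(np.bincount(sub.argmin(axis=0), minlength=len(ids)).argmax())]
        records.append({"fokontany_id": pid, "closest_id": winner, "closest_minutes": mean})
    return pd.DataFrame.from_records(records)


def build_scenarios(
    mean_times: pd.DataFrame,
    roster: pd.DataFrame,
    facilities: pd.DataFrame,
    kind: str,
    method: str = "fokontany_mean",
    fields: dict[str, Grid] | None = None,
    mask: Grid | None = None,
    cell_indices: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assigned and closest travel time per fokontany for one facility kind.

    Eligibility: a facility of the right kind, flagged eligible, and (for
    CSBs) appearing as someone's assigned facility — centers supporting no
    workers are not reassignment targets.
    """
    if kind not in ("CSB", "PA"):
        raise ValueError("kind must be CSB or PA")
    assigned_col = "assigned_csb_id" if kind == "CSB" else "assigned_pa_id"
    fac_kind = facilities[facilities["kind"] == kind]
    assigned_ids = set(roster[assigned_col].dropna())
    eligible = {
        str(r["facility_id"])
        for _, r in fac_kind.iterrows()
        if bool(r["eligible"]) and (kind == "PA" or str(r["facility_id"]) in assigned_ids)
    }

    if method == "fokontany_mean":
        closest = closest_facility(mean_times, eligible)
    elif method == "cell_min":
        if fields is None or mask is None or cell_indices is None:
            raise ValueError("cell_min method needs fields, mask and cell_indices")
        closest = _cell_min_closest(fields, eligible, mask, cell_indices)
    else:
        raise ValueError(f"unknown method {method!r}")

    lookup = mean_times.set_index(["fokontany_id", "facility_id"])["mean_minutes"]
    records = []
    for _, row in roster.iterrows():
        fid = str(row["fokontany_id"])
        aid = row[assigned_col]
        rec = {
            "fokontany_id": fid,
            "facility_kind": kind,
            "assigned_id": None,
            "assigned_minutes": float("nan"),
            "closest_id": None,
            "closest_minutes": float("nan"),
            "excluded": False,
            "exclusion_reason": "",
        }
        if pd.isna(aid) or aid is None or aid == "":
            rec["excluded"] = True
            rec["exclusion_reason"] = "no PA in commune" if kind == "PA" else "no assigned facility"
        elif (fid, str(aid)) not in lookup.index:
            rec["excluded"] = True
            rec["exclusion_reason"] = "assigned facility not mapped"
        else:
            rec["assigned_id"] = str(aid)
            rec["assigned_minutes"] = float(lookup.loc[(fid, str(aid))])
            c = closest[closest["fokontany_id"] == fid]
            if len(c) == 0:
                rec["excluded"] = True
                rec["exclusion_reason"] = "no eligible facility"
            else:
                rec["closest_id"] = str(c.iloc[0]["closest_id"])
                rec["closest_minutes"] = float(c.iloc[0]["closest_minutes"])
                if not np.isfinite(rec["assigned_minutes"]):
                    rec["excluded"] = True
                    rec["exclusion_reason"] = "fokontany unreachable"
        records.append(rec)
    return pd.DataFrame.from_records(records)


def bin_travel_times(minutes) -> dict[str, float]:
    """Proportions in the bins within 2 h / 2–4 h / over 4 h.

    Bins are [0,120], (120,240], (240,∞) minutes: exactly 120 min counts as
    "within 2 hours".  Proportions are over finite values and sum to 1.
    """
    m = np.asarray(pd.Series(minutes).dropna(), dtype=float)
    m = m[np.isfinite(m)]
    if m.size == 0:
        raise ValueError("no finite travel times to bin")
    counts = [
        int(np.sum(m <= 120.0)),
        int(np.sum((m > 120.0) & (m <= 240.0))),
        int(np.sum(m > 240.0)),
    ]
    return {lab: c / m.size for lab, c in zip(BIN_LABELS, counts)}


def district_summary(results: pd.DataFrame, district_map: dict[str, str]) -> pd.DataFrame:
    """Min/max/mean/median travel time in hours per district and pooled.

    One row per (facility kind, district or 'all', scenario in
    assigned/closest); statistics over non-excluded fokontany.
    """
    sub = results[~results["excluded"]].copy()
    sub["district"] = sub["fokontany_id"].map(lambda f: district_map.get(str(f), "unknown"))
    rows = []
    for kind, kdf in sub.groupby("facility_kind"):
        groups = [("all", kdf)] + [(d, g) for d, g in kdf.groupby("district")]
        for district, g in groups:
            for scenario, col in (("assigned", "assigned_minutes"), ("closest", "closest_minutes")):
                h = g[col].astype(float) / 60.0
                rows.append(
                    {
                        "facility_kind": kind,
                        "district": district,
                        "scenario": scenario,
                        "n": len(g),
                        "min_h": float(h.min()),
                        "max_h": float(h.max()),
                        "mean_h": float(h.mean()),
                        "median_h": float(h.median()),
                    }
                )
    return pd.DataFrame.from_records(rows)


def render_report(
    summary: pd.DataFrame,
    results: pd.DataFrame,
    coverage_stats: dict | None = None,
) -> str:
    """Plain-text report: per-district travel-time statistics (hours, 2
    decimals), bin breakdown assigned vs closest (whole percentages), and
    exclusion bookkeeping."""
    lines = ["# Travel time to assigned and closest facilities", ""]
    for kind, kdf in summary.groupby("facility_kind"):
        lines.append(f"## Travel time to {kind} (hours, 1-way, dry season, on foot)")
        lines.append("district        scenario    n    min    max   mean  median")
        for _, r in kdf.sort_values(["district", "scenario"]).iterrows():
            lines.append(
                f"{r['district']:<15} {r['scenario']:<9} {r['n']:>4} "
                f"{r['min_h']:>6.2f} {r['max_h']:>6.2f} {r['mean_h']:>6.2f} {r['median_h']:>7.2f}"
            )
        lines.append("")
        kres = results[(results["facility_kind"] == kind) & (~results["excluded"])]
        for scenario, col in (("assigned", "assigned_minutes"), ("closest", "closest_minutes")):
            bins = bin_travel_times(kres[col])
            lines.append(
                f"{kind} {scenario}: within 2 h {bins['le_2h']:.0%}, "
                f"2-4 h {bins['2_to_4h']:.0%}, over 4 h {bins['gt_4h']:.0%}"
            )
        mis = kres[kres["assigned_id"] != kres["closest_id"]]
        lines.append(f"{kind}: not assigned to closest facility in {len(mis)} of {len(kres)} fokontany")
        n_excl = int(results[(results["facility_kind"] == kind)]["excluded"].sum())
        if n_excl:
            reasons = results[(results["facility_kind"] == kind) & results["excluded"]][
                "exclusion_reason"
            ].value_counts()
            why = ", ".join(f"{v} {k}" for k, v in reasons.items())
            lines.append(f"{kind}: {n_excl} fokontany excluded ({why})")
        lines.append("")
    if coverage_stats:
        lines.append("## Expected coverage per worker")
        lines.append(
            "fokontany below thresholds: "
            f"population {coverage_stats['prop_below_pop']:.0%}, "
            f"area {coverage_stats['prop_below_area']:.0%}, "
            f"both {coverage_stats['prop_below_both']:.0%} "
            f"(n={coverage_stats['n_with_acs']})"
        )
    return "\n".join(lines)
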