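"""Per-zone cell statistics: zone assignment, occupancy fractions,
densities, marker-positive fractions, the RISH+/RISH- proportion
comparison, and a permutation test for zone enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .zonation import TISSUE_ZONES, Zone, ZoneMap


def assign_zones(cells: pd.DataFrame, zone_map: ZoneMap) -> pd.DataFrame:
    """Label every cell with the zone of the pixel containing its centroid.

    Adds ``zone`` (zone name or NA), ``zone_code`` and, when the zone map
    carries a duct mask, a boolean ``on_duct`` convenience flag for the
    bile-duct infiltration count. Cells outside the raster or on background
    get a null zone; they are excluded from zone statistics but stay in the
    table and are counted in ``df.attrs``.
    """
    out = cells.copy()
    if len(out) == 0:
        out["zone"] = pd.Series(dtype="string")
        out["zone_code"] = pd.Series(dtype="Int64")
        return out
    px = zone_map.pixel_size_um
    col = np.floor(out["x_um"].to_numpy(float) / px).astype(int)
    row = np.floor(out["y_um"].to_numpy(float) / px).astype(int)
    h, w = zone_map.shape
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    codes = np.full(len(out), -1, dtype=int)
    codes[inside] = zone_map.labels[row[inside], col[inside]]

    zone_names = np.full(len(out), None, dtype=object)
    for z in TISSUE_ZONES:
        zone_names[codes == int(z)] = z.name
    out["zone"] = pd.array(zone_names, dtype="string")
    out["zone_code"] = pd.array(np.where(codes > 0, codes, pd.NA), dtype="Int64")
    if zone_map.duct is not None:
        on_duct = np.zeros(len(out), dtype=bool)
        on_duct[inside] = zone_map.duct[row[inside], col[inside]]
        out["on_duct"] = on_duct

    n_outside = int((~inside).sum())
    if n_outside:
        warnings.warn(f"{n_outside} cells fall outside the raster; zone set to NA")
    out.attrs["n_outside_raster"] = n_outside
    out.attrs["n_background"] = int((codes == 0).sum())
    return out


def _resolve_selection(cells: pd.DataFrame, selection) -> pd.Series:
    if selection is None:
        return pd.Series(True, index=cells.index)
    if callable(selection):
        return selection(cells).astype(bool)
    return pd.Series(np.asarray(selection, dtype=bool), index=cells.index)


def zone_statistics(
    cells: pd.DataFrame,
    zone_areas: pd.DataFrame,
    selection=None,
    markers: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-zone counts, fractions, densities and marker-positive fractions
    for the selected cells.

    ``selection`` is a boolean mask or a predicate on the cell table; the
    default selects every zoned cell. Fractions are over the selection, so
    they sum to 1; density is count/area per zone. The overall density
    (selection size over total tissue area) is in ``df.attrs``.
    """
    if "zone" not in cells.columns:
        raise ValueError("cells have no zone assignment; run assign_zones first")
    sel = _resolve_selection(cells, selection)
    zoned = cells[sel & cells["zone"].notna()]
    n_sel = len(zoned)
    area_by_zone = dict(zip(zone_areas["zone"], zone_areas["area_mm2"]))
    total_area = zone_areas.attrs.get("tissue_area_mm2",
                                      float(zone_areas["area_mm2"].sum()))
    rows = []
    for z in TISSUE_ZONES:
        in_zone = zoned[zoned["zone"] == z.name]
        n = len(in_zone)
        area = area_by_zone.get(z.name, 0.0)
        if area == 0 and n > 0:
            warnings.warn(f"zone {z.name} has zero area but {n} cells; density is null")
            density = np.nan
        else:
            density = n / area if area > 0 else np.nan
        row = {
            "zone": z.name,
            "n_cells": n,
            "fraction": n / n_sel if n_sel else np.nan,
            "area_mm2": area,
            "density_per_mm2": density,
        }
        for m in markers:
            col = m if m in cells.columns else f"marker_{m}"
            if col not in cells.columns:
                raise ValueError(f"marker column {m!r} not found in cell table")
            row[f"{m}_pos_frac"] = float(in_zone[col].mean()) if n else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_selected"] = n_sel
    df.attrs["tissue_area_mm2"] = total_area
    df.attrs["overall_density_per_mm2"] = n_sel / total_area if total_area else np.nan
    if "on_duct" in cells.columns:
        df.attrs["n_on_duct"] = int(zoned["on_duct"].sum())
    return df


@dataclass
class ProportionTestResult:
    """Two-sided Fisher exact comparison of a marker between two groups."""

    table: tuple[tuple[int, int], tuple[int, int]]  # (pos, neg) x (a, b)
    proportion_a: float
    proportion_b: float
    odds_ratio: float
    p_value: float
    continuity_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "proportion_a": self.proportion_a,
            "proportion_b": self.proportion_b,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "continuity_applied": self.continuity_applied,
        }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def proportion_test(group_a: pd.DataFrame, group_b: pd.DataFrame,
                    marker: str) -> ProportionTestResult:
    """Compare marker-positive proportions between two cell groups.

    Uses the two-sided Fisher exact test on the 2x2 positivity-by-group
    table. The odds ratio is the sample cross-product; a 0.5 continuity
    correction is applied (and flagged) only when a table margin is zero.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    col = marker if marker in group_a.columns else f"marker_{marker}"
    if col not in group_a.columns or col not in group_b.columns:
        raise ValueError(f"marker {marker!r} absent from the cell records")
    pos_a = int(group_a[col].sum())
    pos_b = int(group_b[col].sum())
    neg_a, neg_b = len(group_a) - pos_a, len(group_b) - pos_b
    p = fisher_exact_2x2(pos_a, pos_b, neg_a, neg_b)
    margins = (pos_a + pos_b, neg_a + neg_b, pos_a + neg_a, pos_b + neg_b)
    continuity = any(m == 0 for m in margins)
    if continuity:
        a, b, c, d = (x + 0.5 for x in (pos_a, pos_b, neg_a, neg_b))
    else:
        a, b, c, d = pos_a, pos_b, neg_a, neg_b
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return ProportionTestResult(
        table=((pos_a, pos_b), (neg_a, neg_b)),
        proportion_a=pos_a / len(group_a),
        proportion_b=pos_b / len(group_b),
        odds_ratio=float(odds),
        p_value=p,
        continuity_applied=continuity,
    )


def zone_enrichment_test(
    cells: pd.DataFrame,
    selection,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for zone enrichment of a cell selection.

    The selection must be a subset of the reference population given by
    ``cells`` (e.g. clone-positive cells within all CD8 cells). Per zone,
    the statistic is the observed selected-cell fraction in the zone minus
    its expectation under drawing ``|selection|`` cells from the reference
    without replacement. The one-sided (enrichment) p-value is the
    permutation tail probability with add-one correction; permutations are
    equivalent draws from the multivariate hypergeometric distribution over
    zone counts, so the test is invariant to cell identities and order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if "zone" not in cells.columns:
        raise ValueError("cells have no zone assignment; run assign_zones first")
    sel = _resolve_selection(cells, selection)
    ref = cells[cells["zone"].notna()]
    sel = sel.loc[ref.index]
    k = int(sel.sum())
    if k == 0:
        raise ValueError("selection is empty")
    rng = np.random.default_rng(seed)
    zones = [z.name for z in TISSUE_ZONES]
    ref_counts = np.array([(ref["zone"] == z).sum() for z in zones])
    sel_counts = np.array([((ref["zone"] == z) & sel).sum() for z in zones])
    expected = ref_counts / ref_counts.sum()
    observed = sel_counts / k
    stat = observed - expected

    draws = rng.multivariate_hypergeometric(ref_counts, k, size=n_perm)
    perm_stat = draws / k - expected
    n_ge = (perm_stat >= stat[None, :] - 1e-12).sum(axis=0)
    p = (1 + n_ge) / (n_perm + 1)
    return pd.DataFrame({
        "zone": zones,
        "n_selected": sel_counts,
        "n_reference": ref_counts,
        "observed_fraction": observed,
        "expected_fraction": expected,
        "statistic": stat,
        "p_value": p,
    })
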