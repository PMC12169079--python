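"""Single-cell TCR-clone calling from in situ transcript tables.

Transcripts are rolled up to per-cell per-gene counts; clone-probe counts
in the eligible cell type (CD8 T cells by default) call TCR-positive
cells; bleed-through is quantified as the share of clone-probe transcripts
landing outside the eligible type; marker expression and differential
expression compare the TCR+ and TCR- populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CloneCallConfig:
    clone_probe_names: tuple[str, ...]
    eligible_cell_type: str = "CD8_T"
    min_transcripts: int = 1
    min_qv: float = 20.0

    def validate(self) -> None:
        if not self.clone_probe_names:
            raise ValueError("at least one clone probe is required")
        if self.min_transcripts < 1:
            raise ValueError("min_transcripts must be >= 1")


def aggregate_transcripts(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    min_qv: float = 20.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell per-gene counts of assigned transcripts passing ``min_qv``.

    Returns ``(counts, unassigned)``: a cells-by-features integer frame
    indexed like the cell table (cells without transcripts get zero rows)
    and the per-feature tally of unassigned (null cell id) transcripts.
    Transcripts referencing unknown cell ids raise, listing the offenders.
    """
    cell_ids = pd.Index(cells["cell_id"])
    assigned = transcripts[transcripts["cell_id"].notna()]
    orphans = assigned.loc[~assigned["cell_id"].isin(cell_ids), "cell_id"].unique()
    if len(orphans):
        raise ValueError(f"transcripts reference unknown cell ids: {list(orphans[:10])}")
    ok = assigned[assigned["qv"] >= min_qv]
    counts = (
        ok.groupby(["cell_id", "feature_name"], observed=True).size().unstack(fill_value=0)
        .reindex(cell_ids, fill_value=0)
    )
    counts.index.name = "cell_id"
    unassigned = (
        transcripts[transcripts["cell_id"].isna()]
        .groupby("feature_name", observed=True).size()
    )
    counts.attrs["n_assigned_pass_qv"] = int(len(ok))
    counts.attrs["n_assigned_fail_qv"] = int(len(assigned) - len(ok))
    counts.attrs["n_unassigned"] = int(len(transcripts) - len(assigned))
    return counts, unassigned


def call_tcr_positive(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    config: CloneCallConfig,
) -> tuple[pd.DataFrame, dict]:
    """Call clone-positive cells among the eligible cell type.

    A cell is TCR+ iff it is of the eligible type and its summed
    clone-probe count reaches ``min_transcripts``. The assigned clone is
    the probe with the maximal count; ties are called ``ambiguous`` —
    still TCR+, but excluded from the per-clone frequencies (which are
    fractions of all eligible cells).
    """
    config.validate()
    eligible = cells["cell_type"] == config.eligible_cell_type
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError(f"no cells of eligible type {config.eligible_cell_type!r}")
    probes = [p for p in config.clone_probe_names if p in counts.columns]
    probe_counts = counts[probes].reindex(cells["cell_id"]).fillna(0).to_numpy(int) \
        if probes else np.zeros((len(cells), 0), dtype=int)
    total = probe_counts.sum(axis=1)
    tcr_pos = eligible.to_numpy() & (total >= config.min_transcripts)

    clone = np.full(len(cells), None, dtype=object)
    status = np.where(tcr_pos, "tcr_pos", "tcr_neg").astype(object)
    if probes:
        best = probe_counts.max(axis=1)
        is_tie = (probe_counts == best[:, None]).sum(axis=1) > 1
        arg = np.argmax(probe_counts, axis=1)
        for i in np.nonzero(tcr_pos)[0]:
            if is_tie[i]:
                status[i] = "ambiguous"
            else:
                clone[i] = probes[arg[i]]

    out = cells.copy()
    out["tcr_status"] = status
    out["clone"] = clone
    for j, p in enumerate(probes):
        out[f"n_{p}"] = probe_counts[:, j]

    n_pos = int(tcr_pos.sum())
    per_clone = {
        p: int((out.loc[tcr_pos, "clone"] == p).sum()) for p in config.clone_probe_names
    }
    summary = {
        "n_eligible": n_eligible,
        "n_tcr_pos": n_pos,
        "n_ambiguous": int((status == "ambiguous").sum()),
        "tcr_pos_fraction": n_pos / n_eligible,
        "per_clone_counts": per_clone,
        "per_clone_frequency": {p: c / n_eligible for p, c in per_clone.items()},
    }
    return out, summary


def bleedthrough_fraction(
    transcripts: pd.DataFrame,
    cells: pd.DataFrame,
    clone_probe_names: tuple[str, ...],
    eligible_cell_type: str = "CD8_T",
    min_qv: float = 0.0,
) -> dict:
    """Where do clone-probe transcripts land, by recipient cell type?

    For each probe and pooled over probes, reports the share of *assigned*
    transcripts per recipient cell type, the unassigned share of all probe
    transcripts, and the outside-eligible fraction
    (1 - share assigned to the eligible type).
    """
    type_of = dict(zip(cells["cell_id"], cells["cell_type"]))
    probe_tx = transcripts[transcripts["feature_name"].isin(clone_probe_names)]
    probe_tx = probe_tx[probe_tx["qv"] >= min_qv]

    def summarise(df: pd.DataFrame) -> dict:
        n_total = len(df)
        assigned = df[df["cell_id"].notna()]
        recipients = assigned["cell_id"].map(type_of)
        shares = (recipients.value_counts() / len(assigned)).to_dict() if len(assigned) else {}
        eligible_share = shares.get(eligible_cell_type, 0.0)
        return {
            "n_transcripts": int(n_total),
            "n_assigned": int(len(assigned)),
            "unassigned_share": (n_total - len(assigned)) / n_total if n_total else np.nan,
            "recipient_type_share": {k: float(v) for k, v in shares.items()},
            "eligible_share": float(eligible_share),
            "outside_eligible_fraction": float(1 - eligible_share) if len(assigned) else np.nan,
        }

    result = {"pooled": summarise(probe_tx)}
    for p in clone_probe_names:
        result[p] = summarise(probe_tx[probe_tx["feature_name"] == p])
    return result


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-total count normalisation.

    Each cell's counts are scaled by (median total count over all cells) /
    (cell total); cells with zero total stay zero.
    """
    totals = counts.sum(axis=1).astype(float)
    median_total = float(totals[totals > 0].median()) if (totals > 0).any() else 0.0
    scale = np.where(totals > 0, median_total / totals.replace(0, np.nan), 0.0)
    return counts.mul(scale, axis=0).fillna(0.0)


def expression_summary(
    counts: pd.DataFrame,
    groups: dict[str, pd.Index],
    genes: tuple[str, ...],
) -> pd.DataFrame:
    """Dot-plot style summary: per (group, gene) percent-expressing and
    scaled mean expression.

    ``pct_expressing`` is the fraction of the group's cells with count >= 1.
    Mean expression is the mean of log1p(median-total-normalised counts),
    z-scaled across groups per gene (zero when all groups are equal).
    """
    missing = [g for g in genes if g not in counts.columns]
    if missing:
        raise ValueError(f"genes not in panel: {missing}")
    seen: set = set()
    for name, idx in groups.items():
        dup = seen & set(idx)
        if dup:
            raise ValueError(f"groups are not disjoint (e.g. {list(dup)[:3]})")
        seen |= set(idx)
    norm = np.log1p(normalize_counts(counts))
    rows = []
    for name, idx in groups.items():
        sub_raw = counts.loc[idx, list(genes)]
        sub_norm = norm.loc[idx, list(genes)]
        for g in genes:
            rows.append({
                "group": name,
                "gene": g,
                "pct_expressing": float((sub_raw[g] >= 1).mean()) * 100.0,
                "mean_expression": float(sub_norm[g].mean()),
            })
    df = pd.DataFrame(rows)
    scaled = []
    for g in genes:
        vals = df.loc[df["gene"] == g, "mean_expression"]
        sd = vals.std(ddof=0)
        scaled.append((vals - vals.mean()) / sd if sd > 0 else vals * 0.0)
    df["scaled_mean_expression"] = pd.concat(scaled).sort_index()
    return df


def differential_expression(
    counts_pos: pd.DataFrame,
    counts_neg: pd.DataFrame,
    fc_threshold: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Counts are median-total normalised jointly; log2 fold change is taken
    on group means of the normalised counts (pseudo-count 1e-9); p-values
    come from the two-sided Wilcoxon rank-sum (Mann-Whitney U) test on
    log1p-normalised values, Benjamini-Hochberg adjusted across genes.
    A gene is significant when log2FC > ``fc_threshold`` (up in the
    positive group) and adjusted p < ``alpha``.
    """
    if len(counts_pos) < 3 or len(counts_neg) < 3:
        raise ValueError("each group needs at least 3 cells")
    genes = [g for g in counts_pos.columns if g in counts_neg.columns]
    pooled = pd.concat([counts_pos[genes], counts_neg[genes]])
    norm = normalize_counts(pooled)
    n_pos = len(counts_pos)
    norm_pos, norm_neg = norm.iloc[:n_pos], norm.iloc[n_pos:]
    eps = 1e-9
    log2fc = np.log2((norm_pos.mean() + eps) / (norm_neg.mean() + eps))

    logs_pos = np.log1p(norm_pos.to_numpy())
    logs_neg = np.log1p(norm_neg.to_numpy())
    constant = np.array([
        np.ptp(np.concatenate([logs_pos[:, j], logs_neg[:, j]])) == 0
        for j in range(len(genes))
    ])
    pvals = np.ones(len(genes))
    if (~constant).any():
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(
                logs_pos[:, ~constant], logs_neg[:, ~constant],
                alternative="two-sided", axis=0)
        pvals[~constant] = res.pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    df = pd.DataFrame({
        "gene": genes,
        "log2_fold_change": log2fc.to_numpy(),
        "p_value": pvals,
        "p_adj": p_adj,
        "pct_pos": (counts_pos[genes] >= 1).mean().to_numpy() * 100.0,
        "pct_neg": (counts_neg[genes] >= 1).mean().to_numpy() * 100.0,
    })
    df["significant"] = (df["log2_fold_change"] > fc_threshold) & (df["p_adj"] < alpha)
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)


def mait_coexpression(
    counts: pd.DataFrame,
    gene_a: str = "KLRB1",
    gene_b: str = "TRAV1-2",
) -> dict:
    """Fraction of cells co-expressing two genes (count >= 1 each).

    Used to check whether clone-positive CD8 cells are MAIT-like
    (KLRB1 and TRAV1-2 co-expression).
    """
    for g in (gene_a, gene_b):
        if g not in counts.columns:
            raise ValueError(f"gene {g!r} not in panel")
    a = counts[gene_a] >= 1
    b = counts[gene_b] >= 1
    n = len(counts)
    return {
        "n_cells": n,
        f"frac_{gene_a}": float(a.mean()) if n else np.nan,
        f"frac_{gene_b}": float(b.mean()) if n else np.nan,
        "frac_coexpressing": float((a & b).mean()) if n else np.nan,
    }
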