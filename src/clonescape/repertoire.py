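"""TCRbeta repertoire analysis: clone frequencies, hyperexpansion, sharing
between longitudinal samples, and CDR3 matching against an
antigen-specificity reference.

A *clonotype* is keyed, by default, by the V gene (allele stripped) plus the
CDR3 amino-acid sequence; purely amino-acid or nucleotide keys are available
for platforms whose clone definition differs. A clone is *hyperexpanded*
when its frequency strictly exceeds a threshold (default 1% of all reads in
the sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: valid clone-key conventions
CLONE_KEYS = ("v+aa", "aa", "nt")


def strip_allele(gene: str) -> str:
    """``TRBV19*01`` -> ``TRBV19``; empty/NaN -> empty string."""
    if gene is None or (isinstance(gene, float) and np.isnan(gene)):
        return ""
    return str(gene).split("*", 1)[0].strip()


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "junction_aa", "duplicate_count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("clonotype table is empty")
    ids = records["sample_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"records mix sample ids: {list(ids)}")
    counts = pd.to_numeric(records["duplicate_count"], errors="raise")
    if (counts < 1).any():
        raise ValueError("duplicate_count must be >= 1 for every record")
    bad = records["junction_aa"].map(
        lambda s: not isinstance(s, str) or not s or not set(s) <= AA_ALPHABET
    )
    if bad.any():
        offenders = records.loc[bad, "junction_aa"].head(5).tolist()
        raise ValueError(f"invalid CDR3 amino-acid sequences, e.g. {offenders}")
    return records


def make_clone_key(records: pd.DataFrame, key: str = "v+aa") -> pd.Series:
    """Clone identity string per record under the chosen convention."""
    if key not in CLONE_KEYS:
        raise ValueError(f"clone key must be one of {CLONE_KEYS}, got {key!r}")
    if key == "aa":
        return records["junction_aa"].astype(str)
    if key == "nt":
        if "junction" not in records.columns or records["junction"].isna().any():
            raise ValueError("nucleotide clone key requires a complete 'junction' column")
        return records["junction"].astype(str)
    v = records.get("v_call", pd.Series("", index=records.index))
    return v.map(strip_allele) + "|" + records["junction_aa"].astype(str)


def compute_frequencies(records: pd.DataFrame, key: str = "v+aa") -> pd.DataFrame:
    """Aggregate records by clone key and compute frequencies and ranks.

    Duplicate rows for one clone are summed before frequencies are taken
    (export formats often split a clone across rows). Frequency is the
    clone's read count over the sample total; ranks are 1-based by
    descending frequency with lexicographic clone-key tie-break.

    Returns a DataFrame with columns clone_key, v_call, j_call, junction_aa,
    count, frequency, rank, hyperexpanded (initially all False) and the
    sample id in ``df.attrs["sample_id"]``.
    """
    records = _validate_records(records)
    df = records.copy()
    df["clone_key"] = make_clone_key(df, key=key)
    df["duplicate_count"] = pd.to_numeric(df["duplicate_count"])
    agg = {"duplicate_count": "sum", "junction_aa": "first"}
    for col in ("v_call", "j_call", "junction"):
        if col in df.columns:
            agg[col] = "first"
    summary = df.groupby("clone_key", as_index=False).agg(agg)
    summary = summary.rename(columns={"duplicate_count": "count"})
    total = int(summary["count"].sum())
    if total <= 0:
        raise ValueError("total read count is zero")
    summary["frequency"] = summary["count"] / total
    summary = summary.sort_values(
        ["frequency", "clone_key"], ascending=[False, True]
    ).reset_index(drop=True)
    summary["rank"] = np.arange(1, len(summary) + 1)
    summary["hyperexpanded"] = False
    summary.attrs["sample_id"] = str(records["sample_id"].iloc[0])
    summary.attrs["total_count"] = total
    return summary


def call_hyperexpanded(summary: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Flag clones whose frequency strictly exceeds ``threshold``.

    The comparison is strict ("more than"): a clone at exactly the threshold
    is not hyperexpanded.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    out = summary.copy()
    out["hyperexpanded"] = out["frequency"] > threshold
    out.attrs.update(summary.attrs)
    out.attrs["hyperexpansion_threshold"] = threshold
    out.attrs["n_hyperexpanded"] = int(out["hyperexpanded"].sum())
    return out


@dataclass
class SharingReport:
    """Clone sharing and hyperexpansion persistence between two samples."""

    sample_a: str
    sample_b: str
    shared_clone_keys: tuple[str, ...]
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    n_clones_a: int
    n_clones_b: int
    #: per shared clone: hyper_in_both / hyper_in_a_only / hyper_in_b_only / hyper_in_neither
    persistence: dict[str, str] = field(default_factory=dict)

    @property
    def persistence_counts(self) -> dict[str, int]:
        counts = {
            "hyper_in_both": 0,
            "hyper_in_a_only": 0,
            "hyper_in_b_only": 0,
            "hyper_in_neither": 0,
        }
        for cls in self.persistence.values():
            counts[cls] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "n_shared": self.n_shared,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
            "n_clones_a": self.n_clones_a,
            "n_clones_b": self.n_clones_b,
            "persistence_counts": self.persistence_counts,
            "shared_clone_keys": list(self.shared_clone_keys),
        }


def compare_samples(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> SharingReport:
    """Clone sharing between two repertoire summaries by exact clone key."""
    if len(summary_a) == 0 or len(summary_b) == 0:
        raise ValueError("both summaries must be non-empty")
    keys_a = set(summary_a["clone_key"])
    keys_b = set(summary_b["clone_key"])
    shared = tuple(sorted(keys_a & keys_b))
    hyper_a = set(summary_a.loc[summary_a["hyperexpanded"], "clone_key"])
    hyper_b = set(summary_b.loc[summary_b["hyperexpanded"], "clone_key"])
    persistence = {}
    for k in shared:
        in_a, in_b = k in hyper_a, k in hyper_b
        if in_a and in_b:
            persistence[k] = "hyper_in_both"
        elif in_a:
            persistence[k] = "hyper_in_a_only"
        elif in_b:
            persistence[k] = "hyper_in_b_only"
        else:
            persistence[k] = "hyper_in_neither"
    return SharingReport(
        sample_a=summary_a.attrs.get("sample_id", "a"),
        sample_b=summary_b.attrs.get("sample_id", "b"),
        shared_clone_keys=shared,
        n_shared=len(shared),
        n_unique_a=len(keys_a - keys_b),
        n_unique_b=len(keys_b - keys_a),
        n_clones_a=len(keys_a),
        n_clones_b=len(keys_b),
        persistence=persistence,
    )


def cdr3_distance(a: str, b: str) -> int:
    """Levenshtein edit distance between two CDR3 amino-acid sequences."""
    return edlib.align(a, b, task="distance")["editDistance"]


def match_cdr3(
    summary: pd.DataFrame,
    reference: pd.DataFrame,
    max_edit_distance: int = 1,
    require_v_match: bool = False,
) -> pd.DataFrame:
    """Match repertoire CDR3s against a reference of known specificities.

    Every reference row within ``max_edit_distance`` Levenshtein distance of
    a query CDR3 is returned, sorted by (query, distance, reference id).
    ``v_gene_consistent`` is computed whenever both V calls are present
    (gene level, alleles stripped); with ``require_v_match`` inconsistent
    pairs are dropped.
    """
    if len(reference) == 0:
        raise ValueError("reference table is empty")
    if "cdr3_aa" not in reference.columns:
        raise ValueError("reference table needs a 'cdr3_aa' column")
    if max_edit_distance < 0:
        raise ValueError("max_edit_distance must be >= 0")
    ref = reference.reset_index(drop=True)
    ref_ids = ref["source_id"] if "source_id" in ref.columns else ref.index.astype(str)
    rows = []
    for _, q in summary.iterrows():
        q_seq = q["junction_aa"]
        q_v = strip_allele(q.get("v_call", ""))
        for i, r in ref.iterrows():
            d = edlib.align(q_seq, str(r["cdr3_aa"]), task="distance",
                            k=max_edit_distance)["editDistance"]
            if d < 0:  # beyond k
                continue
            r_v = strip_allele(r.get("v_call", ""))
            v_consistent = bool(q_v and r_v and q_v == r_v) if (q_v and r_v) else None
            if require_v_match and v_consistent is False:
                continue
            rows.append({
                "clone_key": q["clone_key"],
                "query_cdr3_aa": q_seq,
                "reference_id": str(ref_ids[i]),
                "reference_cdr3_aa": r["cdr3_aa"],
                "epitope": r.get("epitope", ""),
                "antigen": r.get("antigen", ""),
                "edit_distance": int(d),
                "v_gene_consistent": v_consistent,
            })
    out = pd.DataFrame(rows, columns=[
        "clone_key", "query_cdr3_aa", "reference_id", "reference_cdr3_aa",
        "epitope", "antigen", "edit_distance", "v_gene_consistent",
    ])
    return out.sort_values(
        ["clone_key", "edit_distance", "reference_id"]
    ).reset_index(drop=True)


def analyze_pair(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    key: str = "v+aa",
    threshold: float = 0.01,
    max_edit_distance: int = 1,
) -> dict:
    """Full repertoire comparison of two samples; convenience wrapper."""
    sa = call_hyperexpanded(compute_frequencies(records_a, key=key), threshold)
    sb = call_hyperexpanded(compute_frequencies(records_b, key=key), threshold)
    report = compare_samples(sa, sb)
    result = {"summary_a": sa, "summary_b": sb, "sharing": report}
    if reference is not None:
        hyper_b = sb[sb["hyperexpanded"]]
        result["matches"] = match_cdr3(hyper_b, reference,
                                       max_edit_distance=max_edit_distance)
    return result
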