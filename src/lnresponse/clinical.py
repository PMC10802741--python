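"""Responder / non-responder labeling and cohort characteristic summaries.

Response to a drug is derived from longitudinal visit series.  The SRI-4
composite calls a patient a responder when, from some visit at least three
months after starting the drug, the SLEDAI has dropped by >= 4 points from
baseline with no clinically meaningful PGA worsening (increase < 0.3) and,
when BILAG flags are recorded, no new BILAG A and at most one new BILAG B
-- and those conditions hold at every later on-drug visit.  The renal
outcome instead requires the urine protein/creatinine ratio (UPCR) to be
reduced and maintained below 500 mg/g from at least three months until the
last visit under treatment.

`summarize_cohort` produces characteristics-table style group summaries
(responders vs non-responders per drug) with Wilcoxon--Mann--Whitney tests
for continuous variables and Fisher's exact test for categorical ones,
aggregated at patient or sample level per variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ResponseLabel", "VariableSpec", "derive_sri4_response",
    "derive_upcr_response", "label_cohort", "summarize_cohort",
    "wilcoxon_test", "fisher_test", "significance_stars",
    "load_table1_counts", "expand_table1_counts",
]

SLEDAI_DROP = 4
PGA_WORSENING = 0.3
UPCR_THRESHOLD = 500.0
MIN_RESPONSE_MONTH = 3.0


@dataclass
class ResponseLabel:
    patient_id: str
    drug: str
    label: str  # "responder" | "non-responder"
    criterion: str  # "SRI4" | "UPCR"
    onset_month: Optional[float] = None
    flags: List[str] = field(default_factory=list)


@dataclass
class VariableSpec:
    name: str
    kind: str  # "continuous" | "categorical"
    level: str = "patient"  # "patient" | "sample"


def _as_visit_frame(visits) -> pd.DataFrame:
    df = pd.DataFrame(visits) if not isinstance(visits, pd.DataFrame) else visits.copy()
    if "visit_month" not in df.columns:
        raise ValueError("visits need a 'visit_month' column")
    return df.sort_values("visit_month", kind="stable").reset_index(drop=True)


def derive_sri4_response(visits, drug: str = "",
                         pga_worsening: float = PGA_WORSENING,
                         use_bilag: bool = True) -> ResponseLabel:
    """SRI-4 sustained-response label from one patient's on-drug visits.

    Responder iff some visit at month >= 3 meets the SRI-4 conditions
    relative to the first on-drug visit and every subsequent visit keeps
    meeting them.  The BILAG clause is evaluated only when BILAG columns are
    present and ``use_bilag`` is set.
    """
    df = _as_visit_frame(visits)
    if len(df) < 2:
        raise ValueError("need at least two on-drug visits")
    if not (df["visit_month"] >= MIN_RESPONSE_MONTH).any():
        raise ValueError(f"no visit at month >= {MIN_RESPONSE_MONTH}")
    patient = str(df["patient_id"].iloc[0]) if "patient_id" in df else ""

    base_sledai = df["sledai"].iloc[0]
    base_pga = df["pga"].iloc[0]
    has_bilag = use_bilag and {"bilag_new_a", "bilag_new_b"} <= set(df.columns)

    ok = ((base_sledai - df["sledai"] >= SLEDAI_DROP)
          & (df["pga"] - base_pga < pga_worsening))
    if has_bilag:
        ok &= (df["bilag_new_a"] == 0) & (df["bilag_new_b"] <= 1)
    ok = ok.to_numpy()

    eligible = df["visit_month"].to_numpy() >= MIN_RESPONSE_MONTH
    sustained_from = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(eligible & sustained_from)
    flags = [] if has_bilag or not use_bilag else ["bilag_absent"]
    if hits.size:
        return ResponseLabel(patient, drug, "responder", "SRI4",
                             float(df["visit_month"].iloc[hits[0]]), flags)
    return ResponseLabel(patient, drug, "non-responder", "SRI4", None, flags)


def derive_upcr_response(visits, drug: str = "",
                         threshold: float = UPCR_THRESHOLD) -> ResponseLabel:
    """Renal response: UPCR reduced and kept below 500 mg/g from month >= 3.

    Patients already below the threshold at baseline who stay below it are
    labeled responder with a ``baseline_below_threshold`` flag.
    """
    df = _as_visit_frame(visits)
    if "upcr" not in df.columns or df["upcr"].notna().sum() < 2:
        raise ValueError("UPCR series missing or too short")
    df = df[df["upcr"].notna()].reset_index(drop=True)
    if not (df["visit_month"] >= MIN_RESPONSE_MONTH).any():
        raise ValueError(f"no UPCR value at month >= {MIN_RESPONSE_MONTH}")
    patient = str(df["patient_id"].iloc[0]) if "patient_id" in df else ""

    below = (df["upcr"] < threshold).to_numpy()
    eligible = df["visit_month"].to_numpy() >= MIN_RESPONSE_MONTH
    sustained_from = np.logical_and.accumulate(below[::-1])[::-1]
    hits = np.flatnonzero(eligible & sustained_from)
    flags = []
    if df["upcr"].iloc[0] < threshold:
        flags.append("baseline_below_threshold")
    if hits.size:
        return ResponseLabel(patient, drug, "responder", "UPCR",
                             float(df["visit_month"].iloc[hits[0]]), flags)
    return ResponseLabel(patient, drug, "non-responder", "UPCR", None, flags)


def label_cohort(cohort: pd.DataFrame, criterion: str = "SRI4") -> pd.DataFrame:
    """Apply the chosen response criterion per (patient, drug)."""
    derive = derive_sri4_response if criterion == "SRI4" else derive_upcr_response
    rows = []
    for (patient, drug), visits in cohort.groupby(["patient_id", "drug"]):
        lab = derive(visits, drug=drug)
        rows.append({"patient_id": patient, "drug": drug, "label": lab.label,
                     "criterion": lab.criterion, "onset_month": lab.onset_month,
                     "flags": ";".join(lab.flags)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical tests

def wilcoxon_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon--Mann--Whitney p: exact for n <= 25 per group
    (tie-free), normal approximation with continuity correction otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and not ties) else "asymptotic"
    return float(scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method).pvalue)


def fisher_test(table) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("Fisher test expects a 2x2 table")
    if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise ValueError("a zero margin makes the table untestable")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cut, mark in [(0.00005, "****"), (0.0005, "***"),
                      (0.005, "**"), (0.05, "*")]:
        if p < cut:
            return mark
    return ""


# ---------------------------------------------------------------------------
# cohort summary

def _aggregate(df: pd.DataFrame, level: str) -> pd.DataFrame:
    if level == "patient":
        return df.groupby("patient_id", sort=False).first().reset_index()
    return df


def summarize_cohort(table: pd.DataFrame,
                     variable_spec: Sequence[VariableSpec]) -> pd.DataFrame:
    """Group summary (responders vs non-responders) per drug and variable.

    Continuous variables report mean (SD) per group and a Wilcoxon p;
    categorical ones report count (percentage) per level with a
    level-vs-rest Fisher p.  Rows with a missing tested value are dropped
    per variable (count recorded in ``n_missing``).
    """
    required = {"patient_id", "drug", "response"}
    if not required <= set(table.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    out = []
    for drug, ddf in table.groupby("drug", sort=False):
        for spec in variable_spec:
            if spec.name not in ddf.columns:
                raise ValueError(f"variable {spec.name!r} absent from table")
            sub = _aggregate(ddf, spec.level)
            n_missing = int(sub[spec.name].isna().sum())
            sub = sub[sub[spec.name].notna()]
            resp = sub[sub["response"] == "responder"]
            nonresp = sub[sub["response"] == "non-responder"]
            if len(resp) == 0 or len(nonresp) == 0:
                raise ValueError(
                    f"empty response group for {spec.name!r} / {drug}")
            base = {"drug": drug, "variable": spec.name, "kind": spec.kind,
                    "level": spec.level, "n_responder": len(resp),
                    "n_nonresponder": len(nonresp), "n_missing": n_missing}
            if spec.kind == "continuous":
                p = wilcoxon_test(resp[spec.name], nonresp[spec.name])
                out.append({**base, "category": "",
                            "responder_value": resp[spec.name].mean(),
                            "responder_spread": resp[spec.name].std(ddof=1),
                            "nonresponder_value": nonresp[spec.name].mean(),
                            "nonresponder_spread": nonresp[spec.name].std(ddof=1),
                            "test": "wilcoxon", "p": p,
                            "stars": significance_stars(p), "flag": ""})
            else:
                levels = sorted(sub[spec.name].astype(str).unique())
                single = len(levels) < 2
                for lev in levels:
                    a = int((resp[spec.name].astype(str) == lev).sum())
                    b = int((nonresp[spec.name].astype(str) == lev).sum())
                    if single:
                        p, flag = np.nan, "single_level_test_skipped"
                    else:
                        p = fisher_test([[a, len(resp) - a],
                                         [b, len(nonresp) - b]])
                        flag = ""
                    out.append({**base, "category": lev,
                                "responder_value": a,
                                "responder_spread": 100.0 * a / len(resp),
                                "nonresponder_value": b,
                                "nonresponder_spread": 100.0 * b / len(nonresp),
                                "test": "fisher", "p": p,
                                "stars": significance_stars(p) if not single else "",
                                "flag": flag})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# packaged characteristics-table fixture (SPARE lupus-nephritis cohort)

def load_table1_counts() -> pd.DataFrame:
    """Published group counts of the SPARE lupus-nephritis cohort
    (categorical characteristics per drug and response group)."""
    with resources.files("lnresponse.data").joinpath(
            "table1_counts.csv").open() as fh:
        return pd.read_csv(fh)


def expand_table1_counts(counts: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Reconstruct a per-sample cohort table from published group counts.

    Binary/categorical variables are assigned so that group-level counts
    match the published table exactly (joint structure across variables is
    arbitrary).  Rows whose count exceeds the group total are skipped with a
    warning.
    """
    counts = load_table1_counts() if counts is None else counts
    frames = []
    totals = counts.groupby(["drug", "group"])[
        ["n_patients", "n_samples"]].first()
    for (drug, group), tot in totals.iterrows():
        n_pat, n_samp = int(tot["n_patients"]), int(tot["n_samples"])
        patients = [f"{drug}_{group[:4]}_{i:03d}" for i in range(n_pat)]
        df = pd.DataFrame({
            "patient_id": np.array(patients)[np.arange(n_samp) % n_pat],
            "drug": drug,
            "response": group,
        })
        sel = counts[(counts["drug"] == drug) & (counts["group"] == group)]
        for var, vdf in sel.groupby("variable", sort=False):
            level = vdf["level"].iloc[0]
            total = n_pat if level == "patient" else n_samp
            if vdf["count"].sum() > total:
                warnings.warn(
                    f"counts for {var!r} ({drug}/{group}) exceed the group "
                    "total; row skipped")
                continue
            if level == "patient":
                values = np.array(["no"] * n_pat, object)
                pos = 0
                for r in vdf.itertuples():
                    values[pos:pos + int(r.count)] = r.category
                    pos += int(r.count)
                pat_map = dict(zip(patients, values))
                df[var] = df["patient_id"].map(pat_map)
            else:
                values = np.array(["no"] * n_samp, object)
                pos = 0
                for r in vdf.itertuples():
                    values[pos:pos + int(r.count)] = r.category
                    pos += int(r.count)
                df[var] = values
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    return merged.fillna("no")
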