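"""Somatic-variant retention filtering and clonality classification.

Retention rules (all thresholds inclusive as printed in the source
study protocol): an SNV is retained iff tumor VAF >= 10% with >= 6
variant reads, and the matched germline shows VAF <= 2.5%, depth >= 25
and <= 5 variant reads.  Indels additionally require tumor depth >= 15.
A mutation is clonal iff its cancer cell fraction exceeds 0.7
(strictly).  CCF estimation itself (requiring purity and copy number)
is upstream; it enters as an input column.
"""

from __future__ import annotations

import pandas as pd

#: Default thresholds; every value is surfaced so sensitivity analyses
#: are one-line edits.
TUMOR_VAF_MIN = 0.10
TUMOR_READS_MIN = 6
GERMLINE_VAF_MAX = 0.025
GERMLINE_DEPTH_MIN = 25
GERMLINE_READS_MAX = 5
INDEL_TUMOR_DEPTH_MIN = 15
CCF_CLONAL_THRESHOLD = 0.7

#: Retention rules in evaluation order; the rejection log names the
#: first failing rule.  Each entry: (rule name, row predicate for PASS).
_RULES = [
    ("tumor VAF", lambda d: d["vaf_tumor"] >= TUMOR_VAF_MIN),
    ("tumor variant reads", lambda d: d["var_reads_tumor"] >= TUMOR_READS_MIN),
    ("germline VAF", lambda d: d["vaf_germline"] <= GERMLINE_VAF_MAX),
    ("germline depth", lambda d: d["depth_germline"] >= GERMLINE_DEPTH_MIN),
    ("germline variant reads",
     lambda d: d["var_reads_germline"] <= GERMLINE_READS_MAX),
    ("indel tumor depth",
     lambda d: (d["variant_class"] != "indel")
     | (d["depth_tumor"] >= INDEL_TUMOR_DEPTH_MIN)),
]

_COUNT_COLUMNS = [
    "var_reads_tumor", "depth_tumor", "var_reads_germline", "depth_germline",
]


def _validate(calls: pd.DataFrame) -> None:
    for col in _COUNT_COLUMNS:
        if (calls[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    if (calls["var_reads_tumor"] > calls["depth_tumor"]).any():
        raise ValueError("tumor variant reads exceed depth")
    if (calls["var_reads_germline"] > calls["depth_germline"]).any():
        raise ValueError("germline variant reads exceed depth")


def filter_somatic(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the somatic retention rules.

    Returns ``(retained, rejection_log)``: the retained subset of the
    input (row order preserved) and a log with one row per rejected
    call naming the first rule it failed.  The filter is a pure per-row
    predicate: order-independent and idempotent, and the retained and
    rejected sets partition the input.
    """
    _validate(calls)
    passes = pd.Series(True, index=calls.index)
    first_fail = pd.Series("", index=calls.index, dtype=object)
    for name, pred in _RULES:
        ok = pred(calls)
        newly_failed = passes & ~ok
        first_fail[newly_failed] = name
        passes &= ok
    retained = calls[passes].copy()
    log = calls.loc[~passes, ["variant_id"]].copy()
    log["failed_rule"] = first_fail[~passes]
    return retained, log.reset_index(drop=True)


def classify_clonality(ccf: float | pd.Series) -> str | pd.Series:
    """Classify mutations as clonal (CCF > 0.7, strictly) or subclonal."""
    if isinstance(ccf, pd.Series):
        if ccf.isna().any():
            raise ValueError("missing CCF values")
        return pd.Series(
            ["clonal" if c > CCF_CLONAL_THRESHOLD else "subclonal" for c in ccf],
            index=ccf.index,
        )
    if ccf is None or pd.isna(ccf):
        raise ValueError("missing CCF value")
    return "clonal" if ccf > CCF_CLONAL_THRESHOLD else "subclonal"
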