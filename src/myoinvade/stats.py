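"""Concordance statistics for staging accuracy against pathology.

Implements the statistical toolkit of the concordance analysis: 2x2
diagnostic summaries with over-/under-staging rates, Pearson chi-square
tests of independence (no continuity correction — this is what reproduces
the published values), Pearson correlation of invasion fractions, one-way
ANOVA, and five-number summaries for box-and-whisker reporting. The
published contingency counts are embedded (``printed_counts.yaml``) so
every derivable published statistic can be recomputed and compared at its
printed precision.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "Chi2Result",
    "DiagnosticSummary",
    "CorrelationResult",
    "AnovaResult",
    "FiveNumber",
    "diagnostic_summary",
    "pearson_chi2",
    "pearson_correlation",
    "oneway_anova",
    "five_number_summary",
    "reproduce_printed_tables",
    "load_printed_counts",
    "CohortReport",
    "cohort_report",
]

STAGES = ("IA", "IB")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("outcome1", "outcome2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.float64)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p: float
    df: int = 1
    low_expected: bool = False  # any expected cell count < 5


@dataclass(frozen=True)
class DiagnosticSummary:
    n: int
    n_compatible: int
    n_over: int
    n_under: int
    accuracy: float
    over_diagnosis_rate: float
    under_diagnosis_rate: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FiveNumber:
    min: float
    q1: float
    median: float
    q3: float
    max: float


def diagnostic_summary(pred_stages, true_stages) -> DiagnosticSummary:
    """Concordance of predicted vs pathological stage over {IA, IB}.

    "Over" is calling IB when pathology says IA; "under" the reverse. The
    over-diagnosis rate is the share of *incompatible* calls that are
    over-staged (e.g. 7 of 10 discordant calls over-staged -> 70%); with no
    discordant calls both rates are reported as 0 with a flag.
    """
    pred = list(pred_stages)
    true = list(true_stages)
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(true)}")
    for s in (*pred, *true):
        if s not in STAGES:
            raise ValueError(f"stage label {s!r} not in {STAGES}")
    n_over = sum(1 for p, t in zip(pred, true) if p == "IB" and t == "IA")
    n_under = sum(1 for p, t in zip(pred, true) if p == "IA" and t == "IB")
    n = len(pred)
    n_comp = n - n_over - n_under
    n_bad = n_over + n_under
    flags: tuple[str, ...] = ()
    if n_bad == 0:
        over_rate = under_rate = 0.0
        flags = ("no_incompatible_cases",)
    else:
        over_rate = n_over / n_bad
        under_rate = n_under / n_bad
    return DiagnosticSummary(
        n=n, n_compatible=n_comp, n_over=n_over, n_under=n_under,
        accuracy=n_comp / n, over_diagnosis_rate=over_rate,
        under_diagnosis_rate=under_rate, flags=flags,
    )


def pearson_chi2(table: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-square test of independence on a 2x2 table, df = 1.

    No Yates continuity correction: the uncorrected statistic is what the
    published values correspond to. Expected counts below 5 set a warning
    flag; a zero row or column margin makes the statistic undefined and
    raises.
    """
    obs = table.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin: chi-square undefined")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return Chi2Result(chi2=chi2, p=p, df=1,
                      low_expected=bool(np.any(expected < 5)))


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test (n - 2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=len(x))


def oneway_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA from the between/within decomposition."""
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(len(a) for a in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    if df_within < 1:
        raise ValueError("need at least one residual degree of freedom")
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    flags: tuple[str, ...] = ()
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_between,
                           df_within=df_within, p=0.0,
                           flags=("zero_within_group_variance",))
    F = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between,
                       df_within=df_within, p=p, flags=flags)


def five_number_summary(values) -> FiveNumber:
    """Min / Q1 / median / Q3 / max with linear-interpolation quartiles.

    Uses the "type 7" convention (the default of most software); the
    ordering invariant min <= Q1 <= median <= Q3 <= max always holds.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty input")
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return FiveNumber(*map(float, q))


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------

def load_printed_counts() -> dict:
    """The embedded published contingency counts, keyed by table."""
    text = resources.files("myoinvade").joinpath("printed_counts.yaml").read_text()
    return yaml.safe_load(text)


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def _match(computed: float, printed: str) -> bool:
    """Compare at the printed precision with round-half-up.

    Half-away-from-zero is demonstrably what the source used: 9/16 = 56.25%
    appears as "56.3", which banker's rounding would print as 56.2.
    """
    d = _decimals(printed)
    q = decimal.Decimal(repr(float(computed))).quantize(
        decimal.Decimal(1).scaleb(-d), rounding=decimal.ROUND_HALF_UP)
    return float(q) == float(printed)


def _counts_to_stages(counts) -> tuple[list[str], list[str]]:
    """Expand a pred-by-path 2x2 count block into stage label vectors."""
    (aa, ab), (ba, bb) = counts
    pred, true = [], []
    for p_stage, row in zip(STAGES, ((aa, ab), (ba, bb))):
        for t_stage, k in zip(STAGES, row):
            pred.extend([p_stage] * k)
            true.extend([t_stage] * k)
    return pred, true


def _compatibility_table(with_counts, without_counts) -> ContingencyTable2x2:
    def split(counts):
        pred, true = _counts_to_stages(counts)
        s = diagnostic_summary(pred, true)
        return s.n_compatible, s.n - s.n_compatible
    cw, iw = split(with_counts)
    co, io = split(without_counts)
    return ContingencyTable2x2(cw, iw, co, io,
                               row_labels=("with", "without"),
                               col_labels=("compatible", "incompatible"))


def reproduce_printed_tables() -> pd.DataFrame:
    """Recompute every published statistic derivable from the printed counts.

    Returns a comparison report with one row per statistic: the recomputed
    value, the printed value, a match flag at printed precision, and
    whether the statistic is expected to match (three published values are
    known not to round to the value their own counts give; these are
    reported but never asserted).
    """
    data = load_printed_counts()
    rows = []

    def add(table, name, quantity, computed, printed, asserted=True):
        rows.append({
            "table": table, "name": name, "quantity": quantity,
            "computed": computed, "printed": float(printed),
            "match": _match(computed, printed), "asserted": asserted,
        })

    for name, block in data["accuracy_tables"].items():
        pred, true = _counts_to_stages(block["counts"])
        assert len(pred) == block["n"]
        s = diagnostic_summary(pred, true)
        add("table2", name, "accuracy_pct", 100 * s.accuracy,
            block["printed_accuracy"])
        add("table2", name, "over_diagnosis_rate_pct",
            100 * s.over_diagnosis_rate, block["printed_over_rate"])

    for name, block in data["reader_comparisons"].items():
        (a, b), (c, d) = block["table"]
        res = pearson_chi2(ContingencyTable2x2(a, b, c, d))
        add("table2_footnote", name, "chi2", res.chi2, block["printed_chi2"],
            asserted=block["asserted"])
        add("table2_footnote", name, "p", res.p, block["printed_p"],
            asserted=block["asserted"])

    for condition, readers in data["condition_effects"].items():
        for name, block in readers.items():
            table = _compatibility_table(block["with"], block["without"])
            for label, printed in zip(("with", "without"),
                                      block["printed_accuracy"]):
                comp, incomp = ((table.a, table.b) if label == "with"
                                else (table.c, table.d))
                add("table3", f"{condition}/{name}", f"accuracy_{label}_pct",
                    100 * comp / (comp + incomp), printed)
            res = pearson_chi2(table)
            add("table3", f"{condition}/{name}", "p", res.p,
                block["printed_p"], asserted=block["asserted"])

    report = pd.DataFrame(rows)
    mismatched = report[report["asserted"] & ~report["match"]]
    if len(mismatched):  # pragma: no cover - would mean a fixture defect
        raise AssertionError(
            f"asserted printed statistics failed to reproduce:\n{mismatched}"
        )
    return report


@dataclass
class CohortReport:
    """Concordance report for one evaluated cohort (published-table shape)."""

    n_evaluated: int
    evaluation_mode: str  # "study-faithful" (validation + test) or "strict"
    summary: DiagnosticSummary
    stage_table: ContingencyTable2x2
    correlation: CorrelationResult | None
    by_leiomyoma: dict[str, DiagnosticSummary] = field(default_factory=dict)
    leiomyoma_chi2: Chi2Result | None = None
    fraction_summaries: dict[str, FiveNumber] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def conservation_ok(self) -> bool:
        s = self.summary
        return s.n_compatible + s.n_over + s.n_under == s.n == self.n_evaluated


def cohort_report(
    pred_stages, true_stages, *,
    pred_fractions=None, true_fractions=None,
    leiomyoma_flags=None, evaluation_mode: str = "study-faithful",
) -> CohortReport:
    """Assemble the full concordance report for an evaluated phantom cohort."""
    summary = diagnostic_summary(pred_stages, true_stages)
    pred = list(pred_stages)
    true = list(true_stages)
    cells = {
        (p, t): sum(1 for pp, tt in zip(pred, true) if pp == p and tt == t)
        for p in STAGES for t in STAGES
    }
    stage_table = ContingencyTable2x2(
        cells[("IA", "IA")], cells[("IA", "IB")],
        cells[("IB", "IA")], cells[("IB", "IB")],
        row_labels=("pred_IA", "pred_IB"), col_labels=("path_IA", "path_IB"),
    )
    correlation = None
    fraction_summaries: dict[str, FiveNumber] = {}
    if pred_fractions is not None and true_fractions is not None:
        pf = np.asarray(pred_fractions, dtype=np.float64)
        tf = np.asarray(true_fractions, dtype=np.float64)
        if len(pf) >= 3 and np.ptp(pf) > 0 and np.ptp(tf) > 0:
            correlation = pearson_correlation(tf, pf)
        compatible = np.array([p == t for p, t in zip(pred, true)])
        if compatible.any():
            fraction_summaries["compatible"] = five_number_summary(tf[compatible])
        if (~compatible).any():
            fraction_summaries["discrepancy"] = five_number_summary(tf[~compatible])
    by_leiomyoma: dict[str, DiagnosticSummary] = {}
    leiomyoma_chi2 = None
    if leiomyoma_flags is not None:
        lm = np.asarray(list(leiomyoma_flags), dtype=bool)
        for label, sel in (("present", lm), ("absent", ~lm)):
            if sel.any():
                by_leiomyoma[label] = diagnostic_summary(
                    [p for p, s in zip(pred, sel) if s],
                    [t for t, s in zip(true, sel) if s],
                )
        if len(by_leiomyoma) == 2:
            w = by_leiomyoma["present"]
            o = by_leiomyoma["absent"]
            try:
                leiomyoma_chi2 = pearson_chi2(ContingencyTable2x2(
                    w.n_compatible, w.n - w.n_compatible,
                    o.n_compatible, o.n - o.n_compatible,
                ))
            except ValueError:
                pass  # degenerate margin (e.g. all correct) — omit the test
    return CohortReport(
        n_evaluated=summary.n,
        evaluation_mode=evaluation_mode,
        summary=summary,
        stage_table=stage_table,
        correlation=correlation,
        by_leiomyoma=by_leiomyoma,
        leiomyoma_chi2=leiomyoma_chi2,
        fraction_summaries=fraction_summaries,
    )
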