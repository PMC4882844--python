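"""Rater-agreement statistics for MFI% measurements.

Implements the single-measure absolute-agreement intraclass correlation
ICC(A,1) under the two-way model ``y_ij = mu + s_i + r_j + e_ij`` (rows =
observation units, columns = repeated measurements), with its F-based 95%
confidence interval using a Satterthwaite degrees-of-freedom approximation;
Bland-Altman limits of agreement; the Portney-Watkins reliability bands;
and the pairing logic that turns a long-format measurement table into
intra-rater (session 1 vs session 2, raters stacked) or inter-rater
(rater 1 vs rater 2 at one session) ratings matrices.

Point estimate:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR, MSC, MSE are the rows, columns and residual mean squares of the
two-way ANOVA without replication.  The consistency form
(MSR - MSE)/(MSR + (k-1) MSE), which ignores systematic column offsets, is
available behind ``form="consistency"`` for comparison.

A statsmodels-style front door is provided by :class:`AgreementStudy`,
whose ``fit()`` returns an :class:`AgreementResults` carrying the overall
ICC, Bland-Altman summary, the stratified table, and a ``summary()`` text
report.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DegenerateDataError, InsufficientDataError
from .io import LEVELS, QUARTILES, SIDES
from .tables import MeasurementTable

#: conventional 95% limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96

UNIT_COLUMNS = ["subject_id", "level", "side", "quartile"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RatingsMatrix:
    """n_units x k grid of repeated MFI% observations.

    ``unit_keys[i]`` identifies row i; for the intra-rater design the rater id
    is appended to the key since each unit contributes one row per rater.
    ``n_dropped`` counts units discarded for incomplete pairs.
    """

    values: np.ndarray
    unit_keys: list[tuple]
    design: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InsufficientDataError("ratings matrix must be 2-D")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise InsufficientDataError(
                f"need at least 2 units and 2 measurements, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InsufficientDataError("ratings matrix contains missing cells")
        self.values = v

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IccResult:
    """ICC point estimate with confidence interval and reliability label."""

    icc: float
    ci_low: float
    ci_high: float
    alpha: float
    n_units: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    label: str
    form: str = "agreement"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")
        if self.label != classify_icc(self.icc):
            raise ValueError("label inconsistent with classification bands")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement for paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


# ---------------------------------------------------------------------------
# ANOVA and ICC
# ---------------------------------------------------------------------------

def anova_two_way(matrix: RatingsMatrix | np.ndarray) -> tuple[float, float, float]:
    """Mean squares (MSR, MSC, MSE) of the two-way layout without replication.

    MSR = k sum_i (row_mean_i - grand)^2 / (n-1)
    MSC = n sum_j (col_mean_j - grand)^2 / (k-1)
    MSE = sum_ij (y_ij - row_mean_i - col_mean_j + grand)^2 / ((n-1)(k-1))
    """
    y = matrix.values if isinstance(matrix, RatingsMatrix) else np.asarray(matrix, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise InsufficientDataError(f"need an n>=2 by k>=2 grid, got shape {y.shape}")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid ** 2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(
    matrix: RatingsMatrix | np.ndarray,
    alpha: float = 0.05,
    form: str = "agreement",
) -> IccResult:
    """Single-measure ICC with a two-sided ``1 - alpha`` confidence interval.

    ``form="agreement"`` (default) penalizes systematic rater offsets;
    ``form="consistency"`` is (MSR - MSE)/(MSR + (k-1) MSE).

    Identical columns with non-constant rows give ICC = 1 with a degenerate
    (1, 1) interval; a fully constant matrix has zero total variance and the
    ICC is undefined (raises :class:`DegenerateDataError`).
    """
    if form not in ("agreement", "consistency"):
        raise ValueError(f"form must be 'agreement' or 'consistency', got {form!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if isinstance(matrix, np.ndarray):
        matrix = RatingsMatrix(matrix, unit_keys=[(i,) for i in range(len(matrix))],
                               design="adhoc")
    n, k = matrix.n_units, matrix.k
    msr, msc, mse = anova_two_way(matrix)

    if msr == 0 and msc == 0 and mse == 0:
        raise DegenerateDataError(
            "all ratings identical: zero total variance, ICC undefined"
        )

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if 1.0 - icc < 1e-12:
        # perfect agreement among non-constant rows: CI collapses to a point
        return IccResult(
            icc=1.0, ci_low=1.0, ci_high=1.0, alpha=alpha, n_units=n, k=k,
            ms_rows=msr, ms_cols=msc, ms_error=mse,
            label=classify_icc(1.0), form=form,
        )

    if form == "consistency":
        # exact F interval for the consistency form
        f_obs = msr / mse if mse > 0 else np.inf
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f2 = f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        fl = f_obs / f1
        fu = f_obs * f2
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else np.inf
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )

    lo = min(lo, icc)
    hi = max(hi, icc)
    return IccResult(
        icc=float(icc), ci_low=float(lo), ci_high=float(hi), alpha=alpha,
        n_units=n, k=k, ms_rows=msr, ms_cols=msc, ms_error=mse,
        label=classify_icc(float(icc)), form=form,
    )


def classify_icc(value: float) -> str:
    """Portney-Watkins reliability bands, half-open lower-inclusive.

    < 0.50 poor; [0.50, 0.75) moderate; [0.75, 0.90) good; [0.90, 1] excellent.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value < 0.50:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.90:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(pairs) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement of paired measurements.

    ``pairs`` is a sequence of (m1, m2); differences are m1 - m2, the SD uses
    the n-1 denominator, and LoA = mean +/- 1.96 SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need at least 2 (m1, m2) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        n_pairs=arr.shape[0],
    )


def implied_mean_difference(loa_low, loa_high, ndigits: int | None = None):
    """Mean difference implied by printed limits of agreement (their midpoint).

    Published LoA are fixed-precision decimals, so the midpoint is computed in
    decimal arithmetic on the printed representations; ``ndigits`` rounds the
    result half-away-from-zero to that many decimals, as tabulated values are.
    """
    lo = Decimal(str(loa_low))
    hi = Decimal(str(loa_high))
    mid = (lo + hi) / 2
    if ndigits is not None:
        mid = mid.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(mid)


# ---------------------------------------------------------------------------
# pairing a long-format table into ratings matrices
# ---------------------------------------------------------------------------

def pair_intra(table: MeasurementTable | pd.DataFrame) -> RatingsMatrix:
    """Intra-rater matrix: one row per (unit, rater) with both sessions.

    For each rater, each (subject, level, side, quartile) unit measured in
    both sessions contributes a (session1, session2) row; rows from all
    raters are stacked.  Units missing a session are dropped and counted.
    """
    df = table.df if isinstance(table, MeasurementTable) else table
    sessions = sorted(df["session_id"].unique())
    if len(sessions) < 2:
        raise InsufficientDataError(
            f"intra-rater pairing needs >=2 sessions, found {sessions}"
        )
    s1, s2 = sessions[0], sessions[1]
    rows, keys, dropped = [], [], 0
    for rater, sub in df.groupby("rater_id", sort=True):
        wide = sub.pivot_table(
            index=UNIT_COLUMNS, columns="session_id", values="mfi_percent",
            aggfunc="first",
        )
        for col in (s1, s2):
            if col not in wide.columns:
                wide[col] = np.nan
        complete = wide[[s1, s2]].dropna()
        dropped += len(wide) - len(complete)
        for unit, row in complete.iterrows():
            rows.append([row[s1], row[s2]])
            keys.append(tuple(unit) + (rater,))
    if not rows:
        raise InsufficientDataError("no unit has both sessions for any rater")
    return RatingsMatrix(np.array(rows), unit_keys=keys, design="intra",
                         n_dropped=dropped)


def pair_inter(
    table: MeasurementTable | pd.DataFrame, session: str | None = None
) -> RatingsMatrix:
    """Inter-rater matrix: one row per unit, (rater1, rater2) at one session.

    ``session`` defaults to the first session in sorted order.  Exactly two
    raters must be present.
    """
    df = table.df if isinstance(table, MeasurementTable) else table
    raters = sorted(df["rater_id"].unique())
    if len(raters) != 2:
        raise InsufficientDataError(
            f"inter-rater pairing needs exactly 2 raters, found {raters}"
        )
    sessions = sorted(df["session_id"].unique())
    if session is None:
        session = sessions[0]
    elif session not in sessions:
        raise InsufficientDataError(
            f"session {session!r} not present; table has {sessions}"
        )
    sub = df[df["session_id"] == session]
    wide = sub.pivot_table(
        index=UNIT_COLUMNS, columns="rater_id", values="mfi_percent", aggfunc="first"
    )
    for r in raters:
        if r not in wide.columns:
            raise InsufficientDataError(f"rater {r!r} absent in session {session!r}")
    complete = wide[list(raters)].dropna()
    dropped = len(wide) - len(complete)
    if len(complete) == 0:
        raise InsufficientDataError("no unit measured by both raters")
    keys = [tuple(u) for u in complete.index]
    return RatingsMatrix(np.array(complete.values, float), unit_keys=keys,
                         design="inter", n_dropped=dropped)


def _pair(df: pd.DataFrame, design: str, session: str | None):
    return pair_intra(df) if design == "intra" else pair_inter(df, session=session)


# ---------------------------------------------------------------------------
# stratified analysis
# ---------------------------------------------------------------------------

#: strata reported by default: every level x quartile cell, each quartile
#: pooled over L1-L5, each side per level and pooled, and the overall pool
#: (overall pools Q1-Q4 only; Qmean rows are derived from them)
_POOLED = "L1-5"


def stratified_reliability(
    table: MeasurementTable,
    design: str,
    alpha: float = 0.05,
    session: str | None = None,
    form: str = "agreement",
) -> pd.DataFrame:
    """ICC for every reporting stratum of the measurement design.

    Returns one row per stratum with columns ``design, level, quartile, side,
    n_units, k, icc, ci_low, ci_high, label, status``.  Strata with too few
    complete pairs (or zero variance) are flagged in ``status`` rather than
    silently dropped.
    """
    if design not in ("intra", "inter"):
        raise ValueError(f"design must be 'intra' or 'inter', got {design!r}")
    df = table.df

    strata: list[dict] = []
    for q in list(QUARTILES) + ["Qmean"]:
        for lv in list(LEVELS) + [_POOLED]:
            strata.append({"level": lv, "quartile": q, "side": "both"})
    for side in SIDES:
        for lv in list(LEVELS) + [_POOLED]:
            strata.append({"level": lv, "quartile": "Q1-4", "side": side})
    strata.append({"level": _POOLED, "quartile": "Q1-4", "side": "both"})

    records = []
    for st in strata:
        sub = df
        if st["level"] != _POOLED:
            sub = sub[sub["level"] == st["level"]]
        if st["quartile"] == "Q1-4":
            sub = sub[sub["quartile"].isin(QUARTILES)]
        else:
            sub = sub[sub["quartile"] == st["quartile"]]
        if st["side"] != "both":
            sub = sub[sub["side"] == st["side"]]

        rec = {"design": design, **st, "n_units": 0, "k": np.nan,
               "icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "label": "", "status": "ok"}
        try:
            matrix = _pair(sub, design, session)
            res = icc_agreement(matrix, alpha=alpha, form=form)
            rec.update(
                n_units=res.n_units, k=res.k, icc=res.icc,
                ci_low=res.ci_low, ci_high=res.ci_high, label=res.label,
            )
        except InsufficientDataError as exc:
            rec["status"] = f"insufficient: {exc}"
        except DegenerateDataError as exc:
            rec["status"] = f"degenerate: {exc}"
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if out.empty:
        raise InsufficientDataError("empty stratification specification")
    return out


# ---------------------------------------------------------------------------
# model-style front door
# ---------------------------------------------------------------------------

class AgreementStudy:
    """Reliability study model over a long-format MFI% measurement table.

    Parameters
    ----------
    table
        :class:`MeasurementTable` (or a DataFrame with the canonical columns).
    design
        ``"intra"`` (rater vs themself across sessions, raters pooled) or
        ``"inter"`` (rater 1 vs rater 2 within one session).
    session
        Session used for the inter-rater comparison (default: first).
    """

    def __init__(self, table, design: str = "intra", session: str | None = None):
        if isinstance(table, pd.DataFrame):
            table = MeasurementTable(table)
        if design not in ("intra", "inter"):
            raise ValueError(f"design must be 'intra' or 'inter', got {design!r}")
        self.table = table
        self.design = design
        self.session = session

    @classmethod
    def from_csv(cls, path, design: str = "intra", session: str | None = None):
        from .tables import read_measurement_table

        return cls(read_measurement_table(path), design=design, session=session)

    def fit(self, alpha: float = 0.05, form: str = "agreement") -> "AgreementResults":
        """Estimate the overall ICC, Bland-Altman summary and stratified table."""
        overall_df = self.table.filter(quartile=list(QUARTILES))
        matrix = _pair(overall_df, self.design, self.session)
        overall = icc_agreement(matrix, alpha=alpha, form=form)
        ba = bland_altman(matrix.values)
        by_stratum = stratified_reliability(
            self.table, self.design, alpha=alpha, session=self.session, form=form
        )
        return AgreementResults(
            model=self, overall=overall, bland_altman=ba,
            by_stratum=by_stratum, matrix=matrix, alpha=alpha, form=form,
        )


@dataclass
class AgreementResults:
    """Fitted agreement statistics; ``summary()`` renders a text report."""

    model: AgreementStudy
    overall: IccResult
    bland_altman: BlandAltmanResult
    by_stratum: pd.DataFrame
    matrix: RatingsMatrix
    alpha: float
    form: str = "agreement"

    def summary(self) -> str:
        o, ba = self.overall, self.bland_altman
        ci_pct = int(round(100 * (1 - self.alpha)))
        lines = [
            f"Agreement study ({self.model.design}-rater, ICC form: {self.form})",
            "=" * 58,
            f"units (Q1-Q4 pooled): {o.n_units}   measurements/unit: {o.k}"
            f"   dropped incomplete: {self.matrix.n_dropped}",
            f"ICC = {o.icc:.3f}  {ci_pct}% CI ({o.ci_low:.3f}, {o.ci_high:.3f})"
            f"  -> {o.label}",
            f"Bland-Altman: mean diff = {ba.mean_diff:.3f}, SD = {ba.sd_diff:.3f}, "
            f"LoA = ({ba.loa_low:.3f}, {ba.loa_high:.3f}), n = {ba.n_pairs}",
            "",
            "Strata (level x quartile/side):",
        ]
        with pd.option_context("display.max_rows", None, "display.width", 120):
            lines.append(
                self.by_stratum.to_string(
                    index=False,
                    float_format=lambda x: f"{x:.3f}",
                    columns=["design", "level", "quartile", "side", "n_units",
                             "icc", "ci_low", "ci_high", "label", "status"],
                )
            )
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None, title: str | None = None):
        """Average-vs-difference scatter with mean and LoA lines."""
        return plot_bland_altman(self.matrix.values, ax=ax, title=title)


def plot_bland_altman(pairs, ax=None, title: str | None = None):
    """Bland-Altman plot: pairwise average (x) vs difference (y), with the
    mean difference and the 95% limits of agreement as horizontal lines."""
    if ax is None:
        from matplotlib.figure import Figure

        fig = Figure(figsize=(6, 4.5))
        ax = fig.add_subplot(111)
    arr = np.asarray(pairs, dtype=float)
    res = bland_altman(arr)
    avg = arr.mean(axis=1)
    diff = arr[:, 0] - arr[:, 1]
    ax.scatter(avg, diff, s=12, alpha=0.6, edgecolors="none")
    ax.axhline(res.mean_diff, color="k", lw=1.2)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("average MFI% of paired measurements")
    ax.set_ylabel("difference in MFI%")
    if title:
        ax.set_title(title)
    return ax
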