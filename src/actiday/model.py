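"""Cohort-level activity analysis as a fitted-model object.

`ActivityCohortModel` binds per-participant average-day profiles to the
participant covariate table; `fit()` residualizes the confounds out of the
participant-level window means, runs the two-tailed pooled t-tests on the
whole-average-day means of the three signal characteristics, and computes
within-group partial correlations between the window means and the
clinical outcomes. The returned `ActivityCohortResults` carries the
estimate tables and a text `summary()`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .features import FEATURE_COLUMNS, WINDOWS, segment_mean
from .stats import independent_ttest, partial_correlation, residualize_confounds

DEFAULT_CONFOUNDS = ("age", "BMI", "NART_IQ")
DEFAULT_CORR_CONFOUNDS = ("age", "BMI", "NART_IQ", "sex")
DEFAULT_OUTCOME_COLS = ("IADL", "SF36_MH", "MADRS", "PAL_errors")


class ActivityCohortModel:
    """Group-difference and correlation model of average-day activity.

    Parameters
    ----------
    profiles : mapping of participant id -> 1440-row average-day profile
        (columns activity_mg, jerk_mg_s, entropy_bits), or a long frame
        with a ``participant_id`` column.
    covariates : participant-level table indexed by participant id with a
        ``group`` column ('LLD'/'control'), confounds and outcome scores.
    """

    def __init__(
        self,
        profiles: dict[str, pd.DataFrame] | pd.DataFrame,
        covariates: pd.DataFrame,
        case_label: str = "LLD",
        control_label: str = "control",
    ) -> None:
        if isinstance(profiles, pd.DataFrame):
            profiles = {
                str(pid): grp.set_index("minute_of_day")
                for pid, grp in profiles.groupby("participant_id")
            }
        self.profiles = dict(profiles)
        self.covariates = covariates
        self.case_label = case_label
        self.control_label = control_label
        if "group" not in covariates.columns:
            raise InputError("covariate table must have a 'group' column")
        both = set(covariates["group"])
        if not {case_label, control_label} <= both:
            raise DataError("both study arms must be present for group tests")

    @classmethod
    def from_tables(cls, profiles_long: pd.DataFrame, covariates: pd.DataFrame, **kw):
        """Build from a long profile table (one row per participant-minute)."""
        return cls(profiles_long, covariates, **kw)

    def window_means(self, windows: tuple[str, ...] = tuple(WINDOWS)) -> pd.DataFrame:
        """Participant-level mean of each feature over each analysis window."""
        rows = {}
        for pid, prof in self.profiles.items():
            row = {}
            for w in windows:
                means = segment_mean(prof, w)
                for feat in FEATURE_COLUMNS:
                    row[f"{feat}:{w}"] = means[feat]
            rows[pid] = row
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "participant_id"
        return out

    def fit(
        self,
        confounds: tuple[str, ...] = DEFAULT_CONFOUNDS,
        corr_confounds: tuple[str, ...] = DEFAULT_CORR_CONFOUNDS,
        outcomes: tuple[str, ...] = DEFAULT_OUTCOME_COLS,
        windows: tuple[str, ...] = tuple(WINDOWS),
    ) -> "ActivityCohortResults":
        """Estimate group differences and outcome correlations.

        Confound effects (default age, BMI, pre-morbid IQ) are removed from
        every window mean by pooled OLS residualization before the group
        t-tests; partial correlations additionally control sex and are
        computed within each group with listwise deletion.
        """
        measures = self.window_means(windows)
        cov = self.covariates.loc[measures.index]
        adjusted = residualize_confounds(measures, cov[list(confounds)])
        is_case = (cov["group"] == self.case_label).to_numpy()

        test_rows = []
        for col in measures.columns:
            feat, w = col.split(":")
            res = independent_ttest(
                adjusted[col].to_numpy()[is_case], adjusted[col].to_numpy()[~is_case]
            )
            test_rows.append(
                {
                    "feature": feat,
                    "window": w,
                    "mean_case": float(np.nanmean(measures[col].to_numpy()[is_case])),
                    "mean_control": float(np.nanmean(measures[col].to_numpy()[~is_case])),
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
        group_tests = pd.DataFrame(test_rows).set_index(["feature", "window"])

        corr_rows = []
        present = [o for o in outcomes if o in cov.columns]
        for grp_name, sel in (("LLD", is_case), ("control", ~is_case)):
            sub = cov.loc[sel, list(corr_confounds)]
            for col in measures.columns:
                feat, w = col.split(":")
                for out_col in present:
                    try:
                        pc = partial_correlation(
                            measures[col].to_numpy()[sel],
                            cov.loc[sel, out_col].to_numpy(),
                            sub,
                            window=w,
                        )
                    except (DataError, InputError):
                        continue  # degenerate or too-small group: omit this pair
                    corr_rows.append(
                        {
                            "group": grp_name,
                            "outcome": out_col,
                            "feature": feat,
                            "window": w,
                            "r": pc.r,
                            "p": pc.p,
                            "n": pc.n,
                        }
                    )
        partial_corr = pd.DataFrame(corr_rows)

        return ActivityCohortResults(
            model=self,
            measures=measures,
            adjusted_measures=adjusted,
            group_tests=group_tests,
            partial_correlations=partial_corr,
            confounds=tuple(confounds),
            corr_confounds=tuple(corr_confounds),
        )


@dataclass
class ActivityCohortResults:
    """Estimates from :meth:`ActivityCohortModel.fit`.

    No multiple-testing correction is applied (exploratory analysis); the
    summary flags this.
    """

    model: ActivityCohortModel
    measures: pd.DataFrame
    adjusted_measures: pd.DataFrame
    group_tests: pd.DataFrame
    partial_correlations: pd.DataFrame
    confounds: tuple[str, ...] = ()
    corr_confounds: tuple[str, ...] = ()

    def group_profile_means(self) -> dict[str, pd.DataFrame]:
        """Minute-of-day group-mean profiles (for plots and localization)."""
        cov = self.model.covariates
        out = {}
        for label in (self.model.case_label, self.model.control_label):
            pids = [p for p in self.model.profiles if cov.loc[p, "group"] == label]
            stacked = pd.concat([self.model.profiles[p][FEATURE_COLUMNS] for p in pids])
            out[label] = stacked.groupby(stacked.index).mean()
        return out

    def summary(self) -> str:
        lines = [
            "Average-day activity analysis",
            "=" * 64,
            f"Participants: {len(self.measures)}  "
            f"(confounds removed: {', '.join(self.confounds)})",
            "",
            "Group differences (two-tailed pooled t on confound-adjusted means)",
            "-" * 64,
        ]
        gt = self.group_tests.reset_index()
        for _, r in gt.iterrows():
            lines.append(
                f"{r['feature']:>13s} {r['window']:>8s}  case {r['mean_case']:8.3f}"
                f"  ctrl {r['mean_control']:8.3f}  t({int(r['df'])}) = {r['t']:6.2f}"
                f"  p = {r['p']:.4g}"
            )
        if len(self.partial_correlations):
            lines += [
                "",
                f"Partial correlations (within group, controlling {', '.join(self.corr_confounds)})",
                "-" * 64,
            ]
            for _, r in self.partial_correlations.iterrows():
                lines.append(
                    f"{r['group']:>8s} {r['outcome']:>11s} ~ {r['feature']:<13s}"
                    f"{r['window']:>8s}  r = {r['r']:+.3f}  p = {r['p']:.4g}  n = {int(r['n'])}"
                )
        lines += ["", "No multiple-testing correction applied (exploratory analysis)."]
        return "\n".join(lines)

    def plot_profiles(self, feature: str = "activity_mg", ax=None):
        """Plot group-mean average-day profiles for one feature."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        for label, prof in self.group_profile_means().items():
            ax.plot(prof.index / 60.0, prof[feature], label=label)
        ax.set_xlabel("hour of day")
        ax.set_ylabel(feature)
        ax.set_xlim(0, 24)
        ax.legend()
        return ax
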