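"""Brain–behavior prediction model: baseline band coherence vs training gain.

The analysis layer is organized as a fitted-model pair in the statsmodels
style.  :class:`TrainingGainModel` is built from per-subject records (each
carrying a baseline coherence table, pre/post tracking scores, and an
optional lesion-exclusion flag); :meth:`TrainingGainModel.fit` runs

* the prediction table: Spearman rank correlation of baseline coherence
  with percent change in the endpoint, for every circuit x band, in the
  full cohort and in the lesion-excluded cohort;
* within-subject change tests: Wilcoxon signed-rank on pre vs post SR and
  ER with the mean +/- sd of the percent change;
* baseline descriptives: coherence vs baseline scores, and SR vs ER.

Per-test alpha is 0.05 with no correction across circuits (a Holm-adjusted
column is reported alongside but is not the headline decision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .behavior import SessionScore, percent_change
from .coherence import CoherenceTable
from .montage import RoiSet
from .stats import spearman, wilcoxon_signed_rank

__all__ = ["SubjectRecord", "TrainingGainModel", "TrainingGainResults"]


@dataclass
class SubjectRecord:
    """One subject's analysis-ready summary."""

    subject_id: str
    coherence: CoherenceTable
    sr_pre: float
    sr_post: float
    er_pre: float
    er_post: float
    excluded_lesion: bool = False

    @property
    def pct_change_sr(self) -> float:
        return percent_change(self.sr_pre, self.sr_post, "higher_better")

    @property
    def pct_change_er(self) -> float:
        return percent_change(self.er_pre, self.er_post, "lower_better")

    @classmethod
    def from_scores(
        cls, subject_id: str, coherence: CoherenceTable,
        pre: SessionScore, post: SessionScore, excluded_lesion: bool = False,
    ) -> "SubjectRecord":
        return cls(
            subject_id=subject_id, coherence=coherence,
            sr_pre=pre.sr, sr_post=post.sr, er_pre=pre.er, er_post=post.er,
            excluded_lesion=excluded_lesion,
        )


def _endpoint_change(rec: SubjectRecord, endpoint: str) -> float:
    if endpoint == "sr":
        return rec.pct_change_sr
    if endpoint == "er":
        return rec.pct_change_er
    raise ValueError(f"unknown endpoint {endpoint!r}")


class TrainingGainModel:
    """Spearman prediction of training-related gains from baseline coherence.

    Parameters
    ----------
    records
        Per-subject :class:`SubjectRecord` list (n >= 4).
    rois
        ROI/circuit configuration; the primary circuit is reported first.
    bands
        Band name -> (f_lo, f_hi); defaults to the bands present in the
        records' coherence tables.
    endpoint
        Primary behavioral endpoint for the prediction table, ``"sr"``
        (success rate, default) or ``"er"`` (error rate).
    """

    def __init__(
        self,
        records: list[SubjectRecord],
        rois: RoiSet,
        bands: dict[str, tuple[float, float]] | None = None,
        endpoint: str = "sr",
        primary_band: str = "high_beta",
    ) -> None:
        if len(records) < 4:
            raise ValueError("need >= 4 subjects")
        ids = [r.subject_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        self.records = list(records)
        self.rois = rois
        self.bands = dict(bands or records[0].coherence.bands)
        self.endpoint = endpoint
        self.primary_band = primary_band

    @classmethod
    def from_frames(
        cls,
        coherence_df: pd.DataFrame,
        scores_df: pd.DataFrame,
        rois: RoiSet,
        lesion_df: pd.DataFrame | None = None,
        **kwargs,
    ) -> "TrainingGainModel":
        """Build from tidy frames.

        ``coherence_df``: subject_id, roi_pair, band, coherence[, n_epochs,
        n_lead_pairs]; ``scores_df``: subject_id, sr_pre, sr_post, er_pre,
        er_post; ``lesion_df`` (optional): subject_id, excluded.
        """
        excl = {}
        if lesion_df is not None:
            excl = dict(zip(lesion_df.subject_id, lesion_df.excluded.astype(bool)))
        bands = {}
        records = []
        for _, row in scores_df.iterrows():
            sid = row.subject_id
            sub = coherence_df[coherence_df.subject_id == sid]
            if sub.empty:
                raise ValueError(f"no coherence rows for subject {sid!r}")
            table = sub.drop(columns=["subject_id"]).reset_index(drop=True)
            if "n_epochs" not in table.columns:
                table["n_epochs"] = -1
            if "n_lead_pairs" not in table.columns:
                table["n_lead_pairs"] = -1
            ct = CoherenceTable(table=table, bands=bands)
            records.append(
                SubjectRecord(
                    subject_id=sid, coherence=ct,
                    sr_pre=float(row.sr_pre), sr_post=float(row.sr_post),
                    er_pre=float(row.er_pre), er_post=float(row.er_post),
                    excluded_lesion=bool(excl.get(sid, False)),
                )
            )
        bands.update({b: (np.nan, np.nan) for b in coherence_df.band.unique()})
        return cls(records, rois, bands=bands, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self) -> "TrainingGainResults":
        pred = self._prediction_table()
        change = self._change_tests()
        baseline = self._baseline_relations()
        return TrainingGainResults(model=self, prediction=pred, change=change, baseline=baseline)

    def _cohorts(self):
        yield "all", self.records
        kept = [r for r in self.records if not r.excluded_lesion]
        yield "lesion_excluded", kept

    def _prediction_table(self) -> pd.DataFrame:
        rows = []
        for cohort, recs in self._cohorts():
            if len(recs) < 4:
                continue
            gains = {ep: [_endpoint_change(r, ep) for r in recs] for ep in ("sr", "er")}
            for circuit in self.rois.circuits:
                cname = f"{circuit[0]}-{circuit[1]}"
                for band in self.bands:
                    coh = [r.coherence.value(circuit, band) for r in recs]
                    res = spearman(coh, gains[self.endpoint])
                    rows.append(
                        {
                            "circuit": cname, "band": band, "cohort": cohort,
                            "endpoint": self.endpoint, "n": res.n,
                            "r": res.r, "p": res.p, "method": res.method,
                        }
                    )
        df = pd.DataFrame(rows)
        # primary circuit/band first; Holm column within each cohort
        prim = f"{self.rois.primary_pair[0]}-{self.rois.primary_pair[1]}"
        df["_prio"] = ~((df.circuit == prim) & (df.band == self.primary_band))
        df = df.sort_values(["cohort", "_prio", "circuit", "band"]).drop(columns="_prio")
        df["p_holm"] = np.nan
        for cohort in df.cohort.unique():
            sel = df.cohort == cohort
            df.loc[sel, "p_holm"] = multipletests(df.loc[sel, "p"], method="holm")[1]
        return df.reset_index(drop=True)

    def _change_tests(self) -> pd.DataFrame:
        rows = []
        recs = self.records
        if len(recs) >= 5:
            for measure, pre_attr, post_attr, direction in (
                ("sr", "sr_pre", "sr_post", "higher_better"),
                ("er", "er_pre", "er_post", "lower_better"),
            ):
                pre = [getattr(r, pre_attr) for r in recs]
                post = [getattr(r, post_attr) for r in recs]
                changes = [percent_change(a, b, direction) for a, b in zip(pre, post)]
                res = wilcoxon_signed_rank(pre, post)
                rows.append(
                    {
                        "measure": measure,
                        "pre_mean": float(np.mean(pre)), "pre_sd": float(np.std(pre, ddof=1)),
                        "post_mean": float(np.mean(post)), "post_sd": float(np.std(post, ddof=1)),
                        "pct_change_mean": float(np.mean(changes)),
                        "pct_change_sd": float(np.std(changes, ddof=1)),
                        "statistic": res.statistic, "p": res.p, "n": res.n,
                        "method": res.method,
                    }
                )
        return pd.DataFrame(rows)

    def _baseline_relations(self) -> pd.DataFrame:
        recs = self.records
        circuit = tuple(self.rois.primary_pair)
        coh = [r.coherence.value(circuit, self.primary_band) for r in recs]
        sr0 = [r.sr_pre for r in recs]
        er0 = [r.er_pre for r in recs]
        rows = []
        for name, x, y in (
            ("coherence_vs_baseline_sr", coh, sr0),
            ("coherence_vs_baseline_er", coh, er0),
            ("baseline_sr_vs_baseline_er", sr0, er0),
        ):
            try:
                res = spearman(x, y)
                rows.append({"relation": name, "r": res.r, "p": res.p, "n": res.n,
                             "method": res.method})
            except ValueError as exc:
                raise ValueError(f"baseline relation {name!r}: {exc}") from exc
        return pd.DataFrame(rows)


@dataclass
class TrainingGainResults:
    """Fitted results: prediction table, change tests, baseline descriptives."""

    model: TrainingGainModel
    prediction: pd.DataFrame
    change: pd.DataFrame
    baseline: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def nobs(self) -> int:
        return len(self.model.records)

    def primary_result(self, cohort: str = "all") -> pd.Series:
        prim = f"{self.model.rois.primary_pair[0]}-{self.model.rois.primary_pair[1]}"
        sel = self.prediction[
            (self.prediction.circuit == prim)
            & (self.prediction.band == self.model.primary_band)
            & (self.prediction.cohort == cohort)
        ]
        if sel.empty:
            raise KeyError(f"no primary result for cohort {cohort!r}")
        return sel.iloc[0]

    def summary(self) -> str:
        model = self.model
        prim = self.primary_result("all")
        lines = [
            "Training-gain prediction from baseline band coherence",
            "=" * 68,
            f"Subjects: {self.nobs}   endpoint: % change in "
            f"{model.endpoint.upper()} score   alpha: 0.05 (uncorrected)",
            f"Primary circuit: {prim.circuit}   band: {model.primary_band}",
            f"Primary Spearman r = {prim.r:+.3f}, p = {prim.p:.4f} ({prim.method}, n={prim.n})",
            "",
            "Prediction table (cohort = all)",
            "-" * 68,
        ]
        sub = self.prediction[self.prediction.cohort == "all"]
        lines.append(f"{'circuit':<16}{'band':<12}{'r':>8}{'p':>10}{'p_holm':>10}")
        for _, row in sub.iterrows():
            lines.append(
                f"{row.circuit:<16}{row.band:<12}{row.r:>+8.3f}{row.p:>10.4f}{row.p_holm:>10.4f}"
            )
        excl = self.prediction[self.prediction.cohort == "lesion_excluded"]
        if not excl.empty and excl.n.iloc[0] < self.nobs:
            pe = self.primary_result("lesion_excluded")
            lines += [
                "",
                f"Lesion-excluded cohort (n={pe.n}): primary r = {pe.r:+.3f}, p = {pe.p:.4f}",
            ]
        if not self.change.empty:
            lines += ["", "Within-subject change (Wilcoxon signed-rank)", "-" * 68]
            for _, row in self.change.iterrows():
                lines.append(
                    f"{row.measure.upper()}: {row.pre_mean:.1f}±{row.pre_sd:.1f} -> "
                    f"{row.post_mean:.1f}±{row.post_sd:.1f}  "
                    f"gain {row.pct_change_mean:+.1f}±{row.pct_change_sd:.1f}%  p={row.p:.4f}"
                )
        lines += ["", f"Tests in prediction table: {len(self.prediction)} "
                      "(per-test alpha, Holm column informational)"]
        return "\n".join(lines)

    def plot_primary(self, ax=None):
        """Scatter of baseline primary-circuit coherence vs endpoint gain."""
        import matplotlib.pyplot as plt

        model = self.model
        circuit = tuple(model.rois.primary_pair)
        coh = [r.coherence.value(circuit, model.primary_band) for r in model.records]
        gain = [_endpoint_change(r, model.endpoint) for r in model.records]
        excl = [r.excluded_lesion for r in model.records]
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.5))
        for flag, color, label in ((False, "k", "included"), (True, "0.6", "lesion-excluded")):
            xs = [c for c, e in zip(coh, excl) if e == flag]
            ys = [g for g, e in zip(gain, excl) if e == flag]
            if xs:
                ax.scatter(xs, ys, c=color, label=label)
        prim = self.primary_result("all")
        ax.set_xlabel(f"baseline {prim.circuit} {model.primary_band} coherence")
        ax.set_ylabel(f"% change in {model.endpoint.upper()} score")
        ax.set_title(f"Spearman r = {prim.r:+.2f}, p = {prim.p:.3f}")
        ax.legend(frameon=False, fontsize=8)
        return ax
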