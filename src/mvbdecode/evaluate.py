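"""Evaluation protocols.

* Leave-one-out cross-validation over trials: each trial in turn is
  flagged as the unknown target and classified from the remaining
  trials. A fold never consults the held-out trial's label except to
  score the prediction.
* Multi-trial protocols: a reference trial with the longest TOTAL-ISI
  is paired (k = 2) with each remaining same-class trial, or fixed
  together with the next-two-longest-ISI trials (k = 3); all targets of
  a run are hypothesized to share one label.
* ISI analysis: Pearson correlation of the per-trial free-energy
  difference (two-model comparison) against PRE-, POST- and TOTAL-ISI.

Inter-stimulus intervals are measured between onsets over *all* trials
regardless of class; first and last trials, which lack a neighbour, are
excluded symmetrically from ISI-based computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import (MVBSettings, TrialBetaSet, classify_glm_weighted,
                       classify_one_model, classify_svm, classify_two_model,
                       estimate_trialwise_betas, rfe_select,
                       DEFAULT_RFE_TARGET, DEFAULT_SVM_C)
from .design import (OMIT, TrialTable, ar1_covariance,
                     build_design_matrix, default_confounds,
                     discriminative_contrast, DEFAULT_DRIFT_CUTOFF_S)
from .masks import fit_voxelwise_glm, t_contrast
from .mvb import MVBOperator
from .simulate import BoldDataset

logger = logging.getLogger("mvbdecode")

METHODS = ("mvb2", "mvb1", "glm", "svm")


@dataclass
class EvalConfig:
    """Everything a cross-validation run needs besides the data."""

    mvb: MVBSettings = field(default_factory=MVBSettings)
    drift_cutoff_s: float = DEFAULT_DRIFT_CUTOFF_S
    ar1_rho: float = 0.2
    svm_C: float = DEFAULT_SVM_C
    rfe_target: int = DEFAULT_RFE_TARGET
    fe_sign: str = "true_minus_other"  # or "abs"


@dataclass
class TrialRecord:
    trial: int
    true_label: str
    predicted: str | None
    correct: bool
    margin: float
    evidence: dict[str, float] = field(default_factory=dict)
    error: str | None = None


@dataclass
class CVReport:
    records: list[TrialRecord]
    method: str

    @property
    def n_trials(self) -> int:
        return len(self.records)

    @property
    def accuracy(self) -> float:
        if not self.records:
            return float("nan")
        return float(np.mean([r.correct for r in self.records]))

    @property
    def by_class(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for cls in sorted({r.true_label for r in self.records}):
            rows = [r.correct for r in self.records if r.true_label == cls]
            out[cls] = float(np.mean(rows))
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_trials": self.n_trials,
            "accuracy": self.accuracy,
            "by_class": self.by_class,
            "records": [
                {"trial": r.trial, "true": r.true_label, "predicted": r.predicted,
                 "correct": r.correct, "margin": r.margin,
                 "evidence": r.evidence, "error": r.error}
                for r in self.records
            ],
        }


class _Fitted:
    """Per-dataset state shared across folds (confounds, noise model,
    operating matrices, trial-wise betas for the SVM route)."""

    def __init__(self, trials: TrialTable, Y: BoldDataset, cfg: EvalConfig):
        self.trials, self.Y, self.cfg = trials, Y, cfg
        self.conf = default_confounds(Y.n_scans, Y.TR, cfg.drift_cutoff_s)
        self.noise = ar1_covariance(Y.n_scans, cfg.ar1_rho)
        self.operator = MVBOperator(Y.data, self.conf.R, self.noise.V)
        self._betas: TrialBetaSet | None = None

    @property
    def betas(self) -> TrialBetaSet:
        # trial-wise betas ignore labels entirely, so they are safe to
        # share across folds
        if self._betas is None:
            base = self.trials.with_targets([])
            self._betas = estimate_trialwise_betas(
                base, self.Y, self.conf, self.cfg.mvb.hrf,
                self.cfg.mvb.microtime_dt)
        return self._betas

    def classify(self, targets: list[int], method: str):
        t = self.trials.with_targets(targets)
        cfg = self.cfg
        if method == "mvb2":
            return classify_two_model(t, self.Y, self.conf, self.noise,
                                      cfg.mvb, operator=self.operator)
        if method == "mvb1":
            return classify_one_model(t, self.Y, self.conf, self.noise,
                                      cfg.mvb, operator=self.operator)
        if method == "glm":
            # T map from a design that omits the targets, so the fold
            # never sees the held-out labels
            hyp = {int(i): OMIT for i in targets}
            X = build_design_matrix(t, hyp, self.Y.TR, self.Y.n_scans,
                                    cfg.mvb.hrf, cfg.mvb.microtime_dt)
            c = discriminative_contrast(X, t.classes)
            tmap = t_contrast(fit_voxelwise_glm(self.Y.data, X, self.conf), c)
            return classify_glm_weighted(t, self.Y, tmap.values, self.conf,
                                         cfg.mvb)
        if method == "svm":
            betas = self.betas
            mask = ~np.isin(betas.trial_indices, targets)
            train = TrialBetaSet(betas=betas.betas[mask],
                                 labels=betas.labels[mask],
                                 trial_indices=betas.trial_indices[mask])
            n_feat = train.betas.shape[1]
            if n_feat > cfg.rfe_target:
                feats = rfe_select(train, cfg.rfe_target, cfg.svm_C)
            else:
                feats = np.arange(n_feat)
            test_rows = betas.betas[np.isin(betas.trial_indices, targets)]
            train_sel = TrialBetaSet(betas=train.betas[:, feats],
                                     labels=train.labels,
                                     trial_indices=train.trial_indices)
            return classify_svm(train_sel, test_rows[:, feats], cfg.svm_C)
        raise ValueError(f"unknown method: {method}")


def loo_crossval(trials: TrialTable, Y: BoldDataset, method: str = "mvb2",
                 config: EvalConfig | None = None,
                 classifier=None) -> CVReport:
    """Leave-one-out over all trials; a failing fold is recorded as
    incorrect with the error message and the run continues.

    ``classifier``, when given, overrides the built-in dispatch: it is
    called as ``classifier(target_index)`` and must return an object
    with ``predicted``, ``margin`` and ``evidence`` attributes (used by
    oracle tests).
    """
    config = config or EvalConfig()
    if trials.target_flags.any():
        raise ValueError("LOO expects every trial to carry a known label")
    state = None if classifier is not None else _Fitted(trials, Y, config)
    records = []
    for i in range(len(trials)):
        true = trials.labels[i]
        try:
            res = classifier(i) if classifier else state.classify([i], method)
            records.append(TrialRecord(
                trial=i, true_label=true, predicted=res.predicted,
                correct=(res.predicted == true), margin=res.margin,
                evidence=dict(res.evidence)))
        except Exception as exc:  # recorded, run continues
            logger.warning("fold %d failed: %s", i, exc)
            records.append(TrialRecord(trial=i, true_label=true, predicted=None,
                                       correct=False, margin=float("nan"),
                                       error=str(exc)))
    return CVReport(records=records, method=method)


# ---------------------------------------------------------------------------
# ISI bookkeeping
# ---------------------------------------------------------------------------

def trial_isis(trials: TrialTable) -> dict[int, tuple[float, float, float]]:
    """(pre, post, total) ISI per trial, onset-to-onset over all trials.

    Boundary trials (no predecessor or successor) are excluded."""
    out = {}
    on = trials.onsets
    for i in range(1, len(trials) - 1):
        pre = float(on[i] - on[i - 1])
        post = float(on[i + 1] - on[i])
        out[i] = (pre, post, pre + post)
    return out


def select_reference_trials(trials: TrialTable, cls: str, k: int = 1) -> list[int]:
    """Top-k same-class trials by TOTAL-ISI (descending); ties go to the
    earlier onset. The first entry is the reference."""
    isis = trial_isis(trials)
    cand = [i for i in isis if trials.labels[i] == cls]
    if len(cand) < k:
        raise ValueError(f"class {cls!r} has only {len(cand)} rankable trials")
    cand.sort(key=lambda i: (-isis[i][2], trials.onsets[i]))
    return cand[:k]


def multi_trial_protocol(trials: TrialTable, Y: BoldDataset, k: int,
                         method: str = "mvb2",
                         config: EvalConfig | None = None,
                         classes: list[str] | None = None,
                         classifier=None) -> CVReport:
    """Joint classification of k same-class targets.

    k = 2: the longest-ISI reference is paired with each remaining
    same-class trial in turn. k = 3: the reference plus the two
    next-longest-ISI trials form one fixed triple per class.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    config = config or EvalConfig()
    state = None if classifier is not None else _Fitted(trials, Y, config)
    records = []
    for cls in classes or trials.classes:
        if k == 2:
            ref = select_reference_trials(trials, cls, 1)[0]
            partners = [i for i in np.flatnonzero(trials.labels == cls)
                        if i != ref]
            runs = [[ref, int(i)] for i in partners]
        else:
            runs = [select_reference_trials(trials, cls, 3)]
        for targets in runs:
            try:
                res = (classifier(targets) if classifier
                       else state.classify(targets, method))
                records.append(TrialRecord(
                    trial=targets[-1], true_label=cls, predicted=res.predicted,
                    correct=(res.predicted == cls), margin=res.margin,
                    evidence=dict(res.evidence)))
            except Exception as exc:
                logger.warning("multi-trial run %s failed: %s", targets, exc)
                records.append(TrialRecord(trial=targets[-1], true_label=cls,
                                           predicted=None, correct=False,
                                           margin=float("nan"), error=str(exc)))
    return CVReport(records=records, method=method)


# ---------------------------------------------------------------------------
# ISI vs free energy
# ---------------------------------------------------------------------------

@dataclass
class ISIRecord:
    trial: int
    pre_isi: float
    post_isi: float
    total_isi: float
    fe_diff: float


def isi_free_energy_analysis(cv: CVReport, trials: TrialTable,
                             fe_sign: str = "true_minus_other"):
    """Correlate per-trial free-energy differences with ISI measures.

    ``fe_diff`` is F(true-label model) - F(alternative model) by
    default, or the absolute difference with ``fe_sign='abs'``. Only
    two-model results carry the needed per-class free energies.
    """
    isis = trial_isis(trials)
    records = []
    for r in cv.records:
        if r.trial not in isis or len(r.evidence) != 2 or r.error:
            continue
        other = next(c for c in r.evidence if c != r.true_label)
        diff = r.evidence[r.true_label] - r.evidence[other]
        if fe_sign == "abs":
            diff = abs(diff)
        pre, post, total = isis[r.trial]
        records.append(ISIRecord(trial=r.trial, pre_isi=pre, post_isi=post,
                                 total_isi=total, fe_diff=diff))
    if len(records) < 4:
        raise ValueError("fewer than 4 usable trials for the ISI analysis")
    fe = np.array([r.fe_diff for r in records])
    out = {}
    for name, vals in (("pre", [r.pre_isi for r in records]),
                       ("post", [r.post_isi for r in records]),
                       ("total", [r.total_isi for r in records])):
        if np.std(fe) == 0 or np.std(vals) == 0:
            out[f"r_{name}"], out[f"p_{name}"] = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(vals, fe)
            out[f"r_{name}"], out[f"p_{name}"] = float(r), float(p)
    return records, out


def paired_ttest(a, b) -> dict[str, float]:
    """Plain paired t summary for comparing accuracies across runs."""
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": float(np.mean(np.asarray(a) - np.asarray(b)))}
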