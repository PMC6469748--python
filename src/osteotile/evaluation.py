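"""Binary ROC/AUC and the hierarchical three-class ROC surface with VUS.

The three tissue classes are evaluated hierarchically, the way a pathologist
reads a slide: first tumor vs non-tumor, then — conditionally, within tumor —
viable vs necrotic.  Each sample therefore carries two scores derived from
its class-probability triple (P_NT, P_NEC, P_VT):

    s_tumor  = P_NEC + P_VT             (evidence the tile is tumor)
    s_viable = P_VT / (P_NEC + P_VT)    (evidence a tumor tile is viable;
                                         0/0 -> 0.5)

For a threshold pair (t1, t2) the decision rule is: NT iff s_tumor < t1;
otherwise NEC iff s_viable < t2, else VT.  Sweeping (t1, t2) traces a surface
of per-class true-positive-rate triples (TPR_NT, TPR_NEC, TPR_VT); the volume
under that surface (VUS) summarises three-class discrimination the way AUC
summarises two-class discrimination.  VUS equals the probability that a
random (NT, NEC, VT) triple is simultaneously correctly ordered —
s_tumor(NT) below both tumor scores and s_viable(NEC) < s_viable(VT) — with
half credit for ties.  VUS = 1 for perfectly informed classification and
1/6 ~= 0.167 for uninformed (label-independent) scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .synth import CLASS_LABELS


@dataclass
class HierarchicalScores:
    """Per-sample hierarchical scores plus the true class label."""

    s_tumor: np.ndarray
    s_viable: np.ndarray
    truth: np.ndarray  # array of "NT"/"NEC"/"VT"

    def __post_init__(self):
        self.s_tumor = np.asarray(self.s_tumor, dtype=float)
        self.s_viable = np.asarray(self.s_viable, dtype=float)
        self.truth = np.asarray(self.truth)
        if not (len(self.s_tumor) == len(self.s_viable) == len(self.truth)):
            raise ValueError("score/label lengths differ")

    def by_class(self, c: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.truth == c
        return self.s_tumor[m], self.s_viable[m]


@dataclass
class RocSurface:
    """TPR triples on a (t1, t2) threshold grid, with the grid-integrated VUS."""

    t1: np.ndarray            # (R1,)
    t2: np.ndarray            # (R2,)
    tpr_nt: np.ndarray        # (R1,)
    tpr_nec: np.ndarray       # (R1, R2)
    tpr_vt: np.ndarray        # (R1, R2)
    vus: float


def binary_roc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC curve and AUC for a binary problem.

    ``labels`` are 0/1 (or boolean); ties receive half credit, i.e. the AUC
    equals the Mann-Whitney rank statistic.
    """
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("binary ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    auc = float(roc_auc_score(labels, scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def hierarchical_scores(probabilities, truth) -> HierarchicalScores:
    """Collapse class-probability triples (NT, NEC, VT order) into the
    two-stage scores; the conditional viable score of a P_tumor = 0 sample
    is defined as 0.5 (no evidence either way)."""
    P = np.asarray(probabilities, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("probabilities must be (n, 3) in NT/NEC/VT order")
    s_tumor = P[:, 1] + P[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        s_viable = np.where(s_tumor > 0, P[:, 2] / np.where(s_tumor > 0, s_tumor, 1.0), 0.5)
    return HierarchicalScores(s_tumor, s_viable, np.asarray(truth))


def _check_classes(samples: HierarchicalScores):
    for c in CLASS_LABELS:
        if not np.any(samples.truth == c):
            raise ValueError(f"class {c} missing from the sample set")


def roc_surface(samples: HierarchicalScores, resolution: int = 201) -> RocSurface:
    """Evaluate the TPR triple on a threshold grid over score quantiles.

    For each (t1, t2): an NT sample is correct iff s_tumor < t1; a NEC sample
    iff s_tumor >= t1 and s_viable < t2; a VT sample iff s_tumor >= t1 and
    s_viable >= t2.  Infinite endpoints are included so the boundary TPR
    triples (0,0,1) and (1,0,0) are attained.
    """
    _check_classes(samples)
    qs = np.linspace(0, 1, max(resolution - 2, 2))
    t1 = np.concatenate(([-np.inf], np.unique(np.quantile(samples.s_tumor, qs)),
                         [np.inf]))
    t2 = np.concatenate(([-np.inf], np.unique(np.quantile(samples.s_viable, qs)),
                         [np.inf]))
    st_nt, _ = samples.by_class("NT")
    st_nec, sv_nec = samples.by_class("NEC")
    st_vt, sv_vt = samples.by_class("VT")

    tpr_nt = (st_nt[None, :] < t1[:, None]).mean(axis=1)
    nec_tumor = st_nec[None, :] >= t1[:, None]          # (R1, n_nec)
    vt_tumor = st_vt[None, :] >= t1[:, None]
    nec_below = sv_nec[None, :] < t2[:, None]           # (R2, n_nec)
    vt_above = sv_vt[None, :] >= t2[:, None]
    tpr_nec = nec_tumor.astype(float) @ nec_below.T.astype(float) / st_nec.size
    tpr_vt = vt_tumor.astype(float) @ vt_above.T.astype(float) / st_vt.size

    v = _integrate_surface(tpr_nt, tpr_nec, tpr_vt)
    return RocSurface(t1, t2, tpr_nt, tpr_nec, tpr_vt, v)


def _integrate_surface(tpr_nt, tpr_nec, tpr_vt) -> float:
    """Stieltjes integration of TPR_VT over the (TPR_NT, TPR_NEC) increments.

    VUS = sum_i dTPR_NT(i) * sum_l dTPR_NEC(i, l) * TPR_VT(i, l), with each
    TPR_VT evaluated at the upper threshold of its cell; converges to the
    triple-counting probability as the grid refines.
    """
    d1 = np.diff(tpr_nt)                       # (R1-1,)
    d2 = np.diff(tpr_nec, axis=1)              # (R1, R2-1)
    inner = (d2 * tpr_vt[:, 1:]).sum(axis=1)   # evaluated at upper t2 edge
    return float((d1 * inner[1:]).sum())


def vus(samples_or_surface, resolution: int | None = None) -> float:
    """Volume under the hierarchical ROC surface.

    Given raw samples, uses the exact triple-counting estimator: the
    probability over all (NT, NEC, VT) triples that s_tumor(NT) is below both
    tumor scores and s_viable(NEC) < s_viable(VT), each strict inequality
    earning half credit on equality (the binary-AUC tie convention).  Given a
    RocSurface (or with ``resolution`` set), integrates the grid instead.
    """
    if isinstance(samples_or_surface, RocSurface):
        return samples_or_surface.vus
    samples: HierarchicalScores = samples_or_surface
    if resolution is not None:
        return roc_surface(samples, resolution).vus
    _check_classes(samples)
    st_nt, _ = samples.by_class("NT")
    st_nec, sv_nec = samples.by_class("NEC")
    st_vt, sv_vt = samples.by_class("VT")
    nt_sorted = np.sort(st_nt)
    n_nt = nt_sorted.size

    # pairwise (NEC j, VT k) grids
    stj = st_nec[:, None]
    stk = st_vt[None, :]
    # tumor stage: credit that an NT score is strictly below BOTH tumor
    # scores, half credit per tied inequality
    lo = np.minimum(stj, stk)
    lt_lo = np.searchsorted(nt_sorted, lo, side="left")
    eq_lo = np.searchsorted(nt_sorted, lo, side="right") - lt_lo
    tie_w = np.where(stj == stk, 0.25, 0.5)
    A = (lt_lo + tie_w * eq_lo) / n_nt
    # viable stage
    svj = sv_nec[:, None]
    svk = sv_vt[None, :]
    B = np.where(svj < svk, 1.0, np.where(svj == svk, 0.5, 0.0))
    return float((A * B).mean())


def vus_brute_force(samples: HierarchicalScores) -> float:
    """Exhaustive enumeration over all n_NT * n_NEC * n_VT triples.

    Independent oracle for the vectorized estimator; O(n^3), tiny inputs only.
    """
    _check_classes(samples)
    st_nt, _ = samples.by_class("NT")
    st_nec, sv_nec = samples.by_class("NEC")
    st_vt, sv_vt = samples.by_class("VT")

    def credit(a, b):  # credit for "a < b"
        return 1.0 if a < b else (0.5 if a == b else 0.0)

    total = 0.0
    for t in range(st_nt.size):
        for j in range(st_nec.size):
            for k in range(st_vt.size):
                total += (credit(st_nt[t], st_nec[j])
                          * credit(st_nt[t], st_vt[k])
                          * credit(sv_nec[j], sv_vt[k]))
    return total / (st_nt.size * st_nec.size * st_vt.size)
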