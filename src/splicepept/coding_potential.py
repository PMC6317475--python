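"""Coding-potential estimation for novel transcripts.

Three classic sequence features feed a logistic model, mirroring the
alignment-free coding/noncoding assessment widely used for transcript
classification:

* **ORF size** — length (nt, stop included) of the longest ATG-initiated,
  stop-terminated open reading frame on the forward strand;
* **Fickett (TESTCODE) score** — positional base bias and composition
  converted through the fixed published lookup tables (external constants,
  not tunable);
* **Hexamer score** — mean log-ratio of in-frame hexamer usage between a
  coding and a noncoding training corpus.

The logistic regression is fit on the three features standardized by the
training means/SDs, with a deterministic optimizer; the decision threshold
is the probability maximizing balanced accuracy on the training data.  The
coding probability (CP) of a transcript is the logistic output; label
"coding" iff CP >= threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np
from sklearn.linear_model import LogisticRegression

_HEXAMERS = ["".join(p) for p in _iterproduct("ACGT", repeat=6)]
_STOPS = {"TAA", "TAG", "TGA"}

# Fickett TESTCODE lookup constants (positional bias and composition),
# fixed external data from the original publication of the statistic.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

COEF_CAP = 30.0


def longest_orf(seq: str) -> tuple[int, int, int]:
    """Longest forward-strand ATG..stop ORF over the three frames.

    Returns (length_nt, start, end); length includes the stop codon and is
    0 (with start=end=0) when no complete ORF exists.  Ties go to the
    leftmost start.
    """
    seq = seq.upper()
    best = (0, 0, 0)
    for frame in range(3):
        orf_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in _STOPS:
                length = i + 3 - orf_start
                if length > best[0] or (length == best[0] and orf_start < best[1]):
                    best = (length, orf_start, i + 3)
                orf_start = None
    return best


def _lookup(value: float, para: list[float], prob: list[float]) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE statistic of a nucleotide sequence (case-insensitive).

    Sequences shorter than 200 nt are scored with a warning; the statistic
    was calibrated on longer stretches.
    """
    seq = seq.upper()
    if len(seq) < 200:
        warnings.warn("Fickett score on sequence < 200 nt", stacklevel=2)
    acgt = sum(seq.count(b) for b in "ACGT")
    if len(seq) > 0 and (len(seq) - acgt) / len(seq) > 0.10:
        warnings.warn("more than 10% non-ACGT characters", stacklevel=2)

    score = 0.0
    for base in "ACGT":
        counts = [seq[p::3].count(base) for p in range(3)]
        position_value = max(counts) / (min(counts) + 1)
        score += (
            _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        content = seq.count(base) / len(seq) if seq else 0.0
        score += (
            _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


def _orf_region(seq: str) -> str:
    """Longest-ORF subsequence, or the whole sequence if no ORF."""
    length, start, end = longest_orf(seq)
    return seq[start:end].upper() if length else seq.upper()


def _count_hexamers(region: str, step: int) -> np.ndarray:
    idx = {h: i for i, h in enumerate(_HEXAMERS)}
    counts = np.zeros(len(_HEXAMERS))
    for i in range(0, len(region) - 5, step):
        j = idx.get(region[i : i + 6])
        if j is not None:
            counts[j] += 1
    return counts


def train_hexamer_table(
    coding: list[str], noncoding: list[str]
) -> dict[str, float]:
    """Log-ratio table over the 4096 hexamers.

    Both corpora are counted the same way — in-frame hexamers (step 3) of
    each sequence's longest ORF, whole sequence when no ORF — with add-one
    smoothing on both sides.  Symmetric counting keeps the table exactly
    antisymmetric under corpus swap and identically zero for identical
    corpora; for CDS input the longest ORF is the annotated reading frame.
    """
    if not coding or not noncoding:
        raise ValueError("both training corpora must be non-empty")
    c_counts = np.zeros(len(_HEXAMERS))
    for seq in coding:
        c_counts += _count_hexamers(_orf_region(seq), step=3)
    n_counts = np.zeros(len(_HEXAMERS))
    for seq in noncoding:
        n_counts += _count_hexamers(_orf_region(seq), step=3)
    c_freq = (c_counts + 1) / (c_counts + 1).sum()
    n_freq = (n_counts + 1) / (n_counts + 1).sum()
    ratio = np.log(c_freq / n_freq)
    return dict(zip(_HEXAMERS, ratio))


def hexamer_score(seq: str, table: dict[str, float]) -> float:
    """Mean table entry over in-frame (step-3) hexamers of the longest ORF,
    falling back to the whole sequence when no ORF is present."""
    region = _orf_region(seq)
    vals = [
        table.get(region[i : i + 6], 0.0) for i in range(0, len(region) - 5, 3)
    ]
    return float(np.mean(vals)) if vals else 0.0


@dataclass
class CPModel:
    hexamer_table: dict[str, float]
    coefficients: np.ndarray  # weights for (orf_size, fickett, hexamer)
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    threshold: float

    def features(self, seq: str) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.array(
                [
                    float(longest_orf(seq)[0]),
                    fickett_score(seq),
                    hexamer_score(seq, self.hexamer_table),
                ]
            )

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "hexamer_table": self.hexamer_table,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CPModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            hexamer_table=d["hexamer_table"],
            coefficients=np.asarray(d["coefficients"]),
            intercept=float(d["intercept"]),
            feature_means=np.asarray(d["feature_means"]),
            feature_sds=np.asarray(d["feature_sds"]),
            threshold=float(d["threshold"]),
        )


def _feature_matrix(seqs: list[str], table: dict[str, float]) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array(
            [
                [float(longest_orf(s)[0]), fickett_score(s), hexamer_score(s, table)]
                for s in seqs
            ]
        )


def train_cp_model(coding: list[str], noncoding: list[str]) -> CPModel:
    """Fit the logistic coding-potential model on labeled transcripts.

    Features are standardized by training means/SDs; the optimizer is
    deterministic (seedless L-BFGS, unpenalized).  Coefficients exceeding
    ``COEF_CAP`` in magnitude (perfect separation) are capped with a
    warning.  The threshold maximizes balanced accuracy on the training
    set; among ties the smallest threshold is kept.
    """
    table = train_hexamer_table(coding, noncoding)
    X = np.vstack(
        [_feature_matrix(coding, table), _feature_matrix(noncoding, table)]
    )
    y = np.concatenate([np.ones(len(coding)), np.zeros(len(noncoding))])
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    Z = (X - means) / sds

    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=100, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    coef = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])
    if np.any(np.abs(coef) > COEF_CAP) or abs(intercept) > COEF_CAP:
        warnings.warn(
            "near-perfect separation: capping logistic coefficients", stacklevel=2
        )
        coef = np.clip(coef, -COEF_CAP, COEF_CAP)
        intercept = float(np.clip(intercept, -COEF_CAP, COEF_CAP))

    probs = 1.0 / (1.0 + np.exp(-(Z @ coef + intercept)))
    candidates = np.unique(np.concatenate([[0.5], probs]))
    best_t, best_ba = 0.5, -1.0
    for t in candidates:
        pred = probs >= t
        tpr = pred[y == 1].mean() if (y == 1).any() else 0.0
        tnr = (~pred[y == 0]).mean() if (y == 0).any() else 0.0
        ba = (tpr + tnr) / 2
        if ba > best_ba + 1e-12:
            best_t, best_ba = float(t), ba
    return CPModel(
        hexamer_table=table,
        coefficients=coef,
        intercept=intercept,
        feature_means=means,
        feature_sds=sds,
        threshold=best_t,
    )


def coding_probability(seq: str, model: CPModel) -> tuple[float, str]:
    """(CP, label): logistic probability of coding and the thresholded call
    ("coding" iff CP >= threshold)."""
    z = (model.features(seq) - model.feature_means) / model.feature_sds
    cp = float(1.0 / (1.0 + np.exp(-(z @ model.coefficients + model.intercept))))
    return cp, ("coding" if cp >= model.threshold else "noncoding")
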