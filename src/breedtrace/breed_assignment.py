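"""Canonical discriminant analysis (CDA) for breed assignment.

The model is the classical multi-class linear discriminant: classes
share a pooled within-class covariance, and an individual's posterior
over classes is

    P(k | x)  proportional to  prior_k * exp(-1/2 (x - mu_k)' S^-1 (x - mu_k))

with genotype dosages (0/1/2 per panel SNP) as the variables.  The
canonical axes — eigenvectors of the between- relative to the
within-class scatter — are retained for low-dimensional inspection;
classification always uses the full shared-covariance rule, which is
equivalent to projecting on all c-1 canonical axes.

A posterior threshold converts low-confidence breed calls to the
hybrid class: an individual whose maximum posterior falls below the
threshold (0.65 by default) is reassigned to ``HY``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

from .datatypes import MISSING, GenotypeDataset, GenotypeError


@dataclass
class DiscriminantModel:
    """A fitted shared-covariance discriminant classifier."""

    classes: list[str]
    class_means: np.ndarray          # c x p
    pooled_within_covariance: np.ndarray  # p x p
    priors: np.ndarray               # c
    canonical_axes: np.ndarray       # p x r, r <= min(p, c-1)
    canonical_eigenvalues: np.ndarray
    ridge: float
    snp_ids: list[str]
    _chol: tuple | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if (self.priors < 0).any():
            raise ValueError("priors must be non-negative")


@dataclass(frozen=True)
class ThresholdRule:
    """Minimum assignation probability below which a call becomes HY."""

    tau: float = 0.65
    fallback_class: str = "HY"

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")


@dataclass
class AssignmentResult:
    """Per-individual posteriors and (optionally thresholded) labels."""

    sample_ids: list[str]
    classes: list[str]
    posteriors: np.ndarray  # n x c, rows sum to 1
    predicted: list[str]
    max_posterior: np.ndarray
    thresholded: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "predicted": self.predicted,
                "max_posterior": self.max_posterior,
            }
        )
        if self.thresholded is not None:
            df["thresholded"] = self.thresholded
        for k, cls in enumerate(self.classes):
            df[f"p_{cls}"] = self.posteriors[:, k]
        return df

    def to_tsv(self, path: str | Path, truth: Sequence[str] | None = None) -> None:
        df = self.to_frame()
        if truth is not None:
            df.insert(1, "truth", list(truth))
        df.to_csv(path, sep="\t", index=False)


def _design_matrix(
    data: GenotypeDataset | np.ndarray, labels: Sequence[str] | None
) -> tuple[np.ndarray, list[str] | None, list[str], list[str]]:
    if isinstance(data, GenotypeDataset):
        if (data.dosage == MISSING).any():
            raise GenotypeError(
                "dataset contains missing genotypes; prune incomplete "
                "samples before discriminant analysis"
            )
        x = data.dosage.astype(np.float64)
        lab = list(labels) if labels is not None else data.populations
        return x, lab, data.sample_ids, data.snp_ids
    x = np.asarray(data, dtype=np.float64)
    lab = list(labels) if labels is not None else None
    ids = [f"obs{i}" for i in range(x.shape[0])]
    return x, lab, ids, [f"v{j}" for j in range(x.shape[1])]


def fit_cda(
    data: GenotypeDataset | np.ndarray,
    labels: Sequence[str] | None = None,
    priors: str | Sequence[float] = "proportional",
    ridge: float = 0.0,
) -> DiscriminantModel:
    """Fit the shared-covariance discriminant model.

    Parameters
    ----------
    data
        Training genotypes (no missing calls) or a plain numeric matrix.
    labels
        Class labels per row; defaults to the dataset's population labels.
    priors
        ``"proportional"`` (training class frequencies), ``"equal"``,
        or an explicit vector in class order (classes sorted).
    ridge
        Relative ridge added to the covariance diagonal
        (``ridge * mean(diag)``); 0 disables regularization.
    """
    x, lab, _, snp_ids = _design_matrix(data, labels)
    if lab is None:
        raise ValueError("labels are required for a plain matrix")
    if len(lab) != x.shape[0]:
        raise ValueError("one label per row required")
    classes = sorted(set(lab))
    if len(classes) < 2:
        raise ValueError("discriminant analysis needs at least 2 classes")
    lab_arr = np.array(lab)
    n, p = x.shape
    c = len(classes)
    means = np.empty((c, p))
    counts = np.empty(c, dtype=int)
    sw = np.zeros((p, p))
    for k, cls in enumerate(classes):
        rows = x[lab_arr == cls]
        counts[k] = rows.shape[0]
        if counts[k] < 2:
            raise ValueError(
                f"class {cls!r} has {counts[k]} member(s); need >= 2"
            )
        means[k] = rows.mean(axis=0)
        centered = rows - means[k]
        sw += centered.T @ centered
    sw /= n - c
    if ridge > 0.0:
        sw = sw + ridge * np.mean(np.diag(sw)) * np.eye(p)

    if isinstance(priors, str):
        if priors == "proportional":
            prior_vec = counts / n
        elif priors == "equal":
            prior_vec = np.full(c, 1.0 / c)
        else:
            raise ValueError(f"unknown priors mode {priors!r}")
    else:
        prior_vec = np.asarray(priors, dtype=float)
        if prior_vec.shape != (c,):
            raise ValueError(f"priors must have length {c}")
        prior_vec = prior_vec / prior_vec.sum()

    try:
        chol = linalg.cho_factor(sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "pooled within-class covariance is singular (e.g. a constant "
            "SNP column); enable ridge regularization via fit_cda(..., "
            "ridge=1e-6)"
        ) from exc

    grand = (counts[:, None] * means).sum(axis=0) / n
    dev = means - grand
    sb = (counts[:, None] * dev).T @ dev / max(c - 1, 1)
    r = min(p, c - 1)
    eigval, eigvec = linalg.eigh(sb, sw)
    order = np.argsort(eigval)[::-1][:r]
    axes = eigvec[:, order]
    return DiscriminantModel(
        classes=classes,
        class_means=means,
        pooled_within_covariance=sw,
        priors=prior_vec,
        canonical_axes=axes,
        canonical_eigenvalues=eigval[order],
        ridge=ridge,
        snp_ids=snp_ids,
        _chol=chol,
    )


def predict(
    model: DiscriminantModel, data: GenotypeDataset | np.ndarray
) -> AssignmentResult:
    """Class posteriors under the shared-covariance Gaussian rule.

    Posterior ties are broken toward the lexicographically smallest
    class label (classes are stored sorted, so argmax does this).
    """
    x, _, sample_ids, snp_ids = _design_matrix(data, None)
    if isinstance(data, GenotypeDataset) and snp_ids != model.snp_ids:
        raise ValueError("dataset SNPs do not match the fitted model's panel")
    if x.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"expected {model.class_means.shape[1]} variables, got {x.shape[1]}"
        )
    chol = model._chol or linalg.cho_factor(model.pooled_within_covariance)
    log_post = np.empty((x.shape[0], len(model.classes)))
    with np.errstate(divide="ignore"):
        log_priors = np.log(model.priors)
    for k in range(len(model.classes)):
        diff = x - model.class_means[k]
        solved = linalg.cho_solve(chol, diff.T)
        maha = np.einsum("ij,ji->i", diff, solved)
        log_post[:, k] = log_priors[k] - 0.5 * maha
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    idx = np.argmax(post, axis=1)
    predicted = [model.classes[i] for i in idx]
    return AssignmentResult(
        sample_ids=sample_ids,
        classes=list(model.classes),
        posteriors=post,
        predicted=predicted,
        max_posterior=post[np.arange(len(idx)), idx],
    )


def apply_threshold(
    result: AssignmentResult, rule: ThresholdRule = ThresholdRule()
) -> AssignmentResult:
    """Reassign low-confidence calls to the fallback (hybrid) class.

    Individuals already predicted as the fallback class are unchanged;
    others keep their predicted class only if their maximum posterior
    reaches ``tau``.
    """
    thresholded = [
        pred
        if pred == rule.fallback_class or mp >= rule.tau
        else rule.fallback_class
        for pred, mp in zip(result.predicted, result.max_posterior)
    ]
    return replace(result, thresholded=thresholded)


@dataclass
class ConfusionSummary:
    """Per-true-class assignment statistics, before and after thresholding."""

    table: pd.DataFrame
    overall_rate: float
    overall_rate_thresholded: float | None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def assignment_summary(
    result: AssignmentResult, truth: Sequence[str]
) -> ConfusionSummary:
    """Summarize assignments against truth labels.

    Reports, per true class: correct counts and rates for the raw
    discriminant call and (when present) the thresholded call, the
    mean and lowest posterior assigned to the true class, and the
    destination labels of wrong calls.
    """
    truth = list(truth)
    if len(truth) != len(result.sample_ids):
        raise ValueError(
            f"{len(truth)} truth labels for {len(result.sample_ids)} individuals"
        )
    if not truth:
        raise GenotypeError("cannot summarize an empty cohort")
    cls_index = {c: k for k, c in enumerate(result.classes)}
    rows = []
    order = sorted(set(truth))
    for cls in order:
        idx = [i for i, t in enumerate(truth) if t == cls]
        n_total = len(idx)
        correct = [i for i in idx if result.predicted[i] == cls]
        wrong = sorted(
            result.predicted[i] for i in idx if result.predicted[i] != cls
        )
        if cls in cls_index:
            true_post = result.posteriors[idx, cls_index[cls]]
            mean_p, min_p = float(true_post.mean()), float(true_post.min())
        else:
            mean_p = min_p = float("nan")
        row = {
            "true_class": cls,
            "n_total": n_total,
            "n_correct_cda": len(correct),
            "rate_cda": len(correct) / n_total,
            "mean_true_posterior": mean_p,
            "min_true_posterior": min_p,
            "wrong_destinations": ",".join(wrong),
        }
        if result.thresholded is not None:
            corr_t = sum(result.thresholded[i] == cls for i in idx)
            row["n_correct_thresholded"] = corr_t
            row["rate_thresholded"] = corr_t / n_total
            row["wrong_destinations_thresholded"] = ",".join(
                sorted(
                    result.thresholded[i]
                    for i in idx
                    if result.thresholded[i] != cls
                )
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("true_class")
    overall = sum(p == t for p, t in zip(result.predicted, truth)) / len(truth)
    overall_t = None
    if result.thresholded is not None:
        overall_t = sum(
            p == t for p, t in zip(result.thresholded, truth)
        ) / len(truth)
    return ConfusionSummary(table, overall, overall_t)
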