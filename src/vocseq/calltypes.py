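"""Call-type discovery and transition-structure comparison.

Calls are clustered into discrete types by a Gaussian mixture model on the
two principal components of a standardized 2-D acoustic feature pair
(activation: duration x maxfreq; modulation: freqslope x entropy).  The
number of types is selected by mean silhouette over a range of candidate
k, with AIC reported as a diagnostic.  Each session then becomes a
sequence of call types, summarized by a k x k transition table.

Two transition tables are compared with a bounded normalized-mutual-
information similarity: take a uniformly random binary variable T naming
one of the two tables and the cell variable E ~ that table's
count-normalized (from, to) distribution, then

    similarity = 1 - MI(T; E) / H(T),

which equals 1 minus the Jensen-Shannon divergence (in bits) between the
two cell distributions: 1 for identical tables, 0 for disjoint supports.
Statistical significance of a between-group difference is assessed by a
label permutation test on the pooled call list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

AXIS_PARAMS = {
    "activation": ("duration_s", "maxfreq_hz"),
    "modulation": ("freqslope_hz", "entropy_bits"),
}


# ---------------------------------------------------------------------------
# Clustering: mixture model on principal components, silhouette selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSelection:
    """A fitted call-type model and the evidence for its chosen k."""

    chosen_k: int
    table: pd.DataFrame            # columns k, silhouette, aic
    model: GaussianMixture
    feature_mean: np.ndarray
    feature_std: np.ndarray
    pca: PCA
    n_repeats: int
    seed: int

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Standardize and rotate raw features into the fitted PC space."""
        z = (np.asarray(features, float) - self.feature_mean) / self.feature_std
        return self.pca.transform(z)


def axis_features(seqs, axis: str) -> tuple[np.ndarray, list[int]]:
    """Pool one 2-D feature pair over sequences.

    Returns the stacked n x 2 feature matrix and the per-sequence lengths
    (for splitting pooled labels back into sessions).
    """
    xp, yp = AXIS_PARAMS[axis]
    cols, lengths = [], []
    for seq in seqs:
        cols.append(np.column_stack([seq.param(xp), seq.param(yp)]))
        lengths.append(len(seq))
    return np.vstack(cols), lengths


def select_cluster_model(
    features: np.ndarray,
    k_range: Sequence[int] = range(2, 21),
    n_repeats: int = 10,
    seed: int = 0,
) -> ClusterSelection:
    """Fit mixtures for each candidate k and choose by mean silhouette.

    Features are standardized to zero mean / unit variance and rotated to
    principal components; each k is fitted ``n_repeats`` times from random
    initial conditions with the best fit by likelihood retained.  The
    chosen k maximizes the silhouette of the hard assignments (ties break
    to the smaller k); the AIC curve is kept as a diagnostic.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 2:
        raise ValueError("features must be an n x 2 array")
    k_range = list(k_range)
    n = len(features)
    if n < max(k_range) + 1:
        raise ValueError(
            f"n={n} too small for k_range up to {max(k_range)} (need >= {max(k_range) + 1})"
        )
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    z = (features - mean) / std
    pca = PCA(n_components=2, random_state=seed).fit(z)
    pcs = pca.transform(z)

    rows, fits = [], {}
    for k in k_range:
        gm = _fit_mixture(pcs, k, n_repeats, seed)
        labels = gm.predict(pcs)
        sil = (
            float(silhouette_score(pcs, labels))
            if len(np.unique(labels)) > 1
            else float("nan")
        )
        rows.append((k, sil, float(gm.aic(pcs))))
        fits[k] = gm
    table = pd.DataFrame(rows, columns=["k", "silhouette", "aic"])

    valid = table.dropna(subset=["silhouette"])
    if valid.empty:
        raise RuntimeError("no candidate k produced at least two occupied clusters")
    # idxmax returns the first (smallest-k) row at a tie
    chosen_k = int(valid.loc[valid["silhouette"].idxmax(), "k"])
    return ClusterSelection(
        chosen_k=chosen_k,
        table=table,
        model=fits[chosen_k],
        feature_mean=mean,
        feature_std=std,
        pca=pca,
        n_repeats=n_repeats,
        seed=seed,
    )


def _fit_mixture(pcs: np.ndarray, k: int, n_repeats: int, seed: int) -> GaussianMixture:
    # reg_covar acts as the variance floor; escalate once if the fit is
    # numerically singular, then give up.
    for reg in (1e-6, 1e-3):
        try:
            return GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=n_repeats,
                reg_covar=reg,
                random_state=seed,
                max_iter=300,
            ).fit(pcs)
        except Exception as exc:  # pragma: no cover - singular-fit fallback
            last = exc
    raise RuntimeError(f"mixture fit failed for k={k} despite variance floor: {last}")


def assign_types(selection: ClusterSelection, features: np.ndarray) -> np.ndarray:
    """Label calls 1..k by maximum posterior component probability.

    ``np.argmax`` resolves posterior ties to the lower component index, so
    a point equidistant between two identical-weight components gets the
    smaller label deterministically.
    """
    pcs = selection.transform(features)
    post = selection.model.predict_proba(pcs)
    return np.argmax(post, axis=1) + 1


def typed_sequences(selection: ClusterSelection, seqs, axis: str) -> list[np.ndarray]:
    """Per-session call-type label arrays for one analysis axis."""
    features, lengths = axis_features(seqs, axis)
    labels = assign_types(selection, features)
    out, pos = [], 0
    for ln in lengths:
        out.append(labels[pos:pos + ln])
        pos += ln
    return out


# ---------------------------------------------------------------------------
# Transition tables and NMI similarity
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """k x k counts of call-type successions (row = from, column = to)."""

    k: int
    counts: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized counts; all-zero (unvisited) rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, self.counts / np.where(totals == 0, 1, totals), 0.0)
        return p

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        probs = self.probabilities
        rows = [
            (i + 1, j + 1, int(self.counts[i, j]), float(probs[i, j]))
            for i in range(self.k)
            for j in range(self.k)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count", "prob"])


def build_transition_table(label_seqs, k: int) -> TransitionTable:
    """Count consecutive (from, to) call-type pairs.

    ``label_seqs`` is one label array or a list of them (one per session);
    transitions never span a session boundary, so pooling m sessions of
    total length n yields n - m transitions.  A session shorter than 2
    contributes nothing (an empty table is valid, not an error).
    """
    if np.ndim(label_seqs[0]) == 0:
        label_seqs = [label_seqs]
    counts = np.zeros((k, k), dtype=int)
    for labels in label_seqs:
        labels = np.asarray(labels, dtype=int)
        if (labels < 1).any() or (labels > k).any():
            raise ValueError(f"labels must lie in 1..{k}")
        if len(labels) < 2:
            continue
        np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    return TransitionTable(k=k, counts=counts)


def _jsd_similarity(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """1 - Jensen-Shannon divergence (bits) between flattened cell
    distributions; equivalently 1 - MI(T;E)/H(T) for the uniform binary
    table-identity variable T."""
    sa, sb = counts_a.sum(), counts_b.sum()
    if sa == 0 and sb == 0:
        logger.info("both transition tables empty; similarity defined as 1")
        return 1.0
    if sa == 0 or sb == 0:
        logger.info("one transition table empty; similarity defined as 1")
        return 1.0
    pa = counts_a / sa
    pb = counts_b / sb
    m = 0.5 * (pa + pb)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    jsd = h(m) - 0.5 * (h(pa) + h(pb))
    return float(np.clip(1.0 - jsd, 0.0, 1.0))


def nmi_similarity(table_a: TransitionTable, table_b: TransitionTable) -> float:
    """Bounded similarity in [0, 1] between two transition tables.

    1 for identical count distributions, 0 for disjoint supports.
    Symmetric, and invariant to any simultaneous relabeling of call types
    applied to both tables.
    """
    if table_a.k != table_b.k:
        raise ValueError("tables must share the same number of call types")
    return _jsd_similarity(table_a.counts.ravel().astype(float),
                           table_b.counts.ravel().astype(float))


def within_table_nmi(table: TransitionTable) -> float:
    """Diagnostic: NMI between the from-type and to-type of one table.

    Measures how predictive the current call type is of the next
    (arithmetic-mean normalization); not used by the permutation test.
    """
    c = table.counts.astype(float)
    total = c.sum()
    if total == 0:
        return 0.0
    pij = c / total
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    mask = pij > 0
    mi = float(
        (pij[mask] * np.log2(pij[mask] / np.outer(pi, pj)[mask])).sum()
    )
    denom = 0.5 * (h(pi) + h(pj))
    return mi / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Permutation test on pooled call labels
# ---------------------------------------------------------------------------

@dataclass
class NMIResult:
    """Outcome of the between-group transition-structure permutation test."""

    observed_nmi: float
    null_nmis: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    unit: str
    alpha: float = 0.05
    groups: tuple = ()

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "observed_nmi": self.observed_nmi,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "unit": self.unit,
            "alpha": self.alpha,
            "significant": self.significant,
            "groups": list(self.groups),
        }


def _group_table_counts(types0, session_codes, member, k):
    idx = np.flatnonzero(member)
    if len(idx) < 2:
        return np.zeros(k * k)
    a, b = idx[:-1], idx[1:]
    ok = session_codes[a] == session_codes[b]
    return np.bincount(types0[a[ok]] * k + types0[b[ok]], minlength=k * k).astype(float)


def permutation_test(
    types: Sequence[int],
    groups: Sequence,
    sessions: Sequence | None = None,
    *,
    n_perm: int = 10_000,
    seed: int | None = None,
    unit: Literal["block", "call", "transition"] = "block",
    block_len: int = 10,
    alpha: float = 0.05,
) -> NMIResult:
    """Permutation test for a difference between two groups' transition
    tables, using the NMI similarity as the test statistic.

    ``types``, ``groups`` and ``sessions`` describe the pooled,
    chronologically ordered call list (one entry per call).  The observed
    statistic is the similarity between the two groups' transition tables;
    under each permutation the group labels are rearranged over the pooled
    list (group sizes preserved) and per-group transitions are recounted
    between consecutive calls sharing the permuted label within a session.
    The p-value is one-sided toward dissimilarity — the proportion of null
    similarities as low as or lower than (more different tables than) the
    observed — with the standard +1 correction:
    ``p = (#{null <= obs} + 1) / (n_perm + 1)``.  Ties count as extreme,
    the conservative convention that keeps the test exact for discrete
    statistics.

    Call-type sequences are serially dependent, so freely shuffling
    individual calls (``unit="call"``) breaks the dependence structure and
    is anti-conservative; the default shuffles contiguous blocks of
    ``block_len`` calls, which preserves local dependence in the null
    draws while still mixing labels.  ``unit="transition"`` permutes the
    pooled observed transitions themselves between the groups.
    """
    types = np.asarray(types)
    groups = np.asarray(groups)
    if sessions is None:
        sessions = groups
    sessions = np.asarray(sessions)
    if not (len(types) == len(groups) == len(sessions)):
        raise ValueError("types, groups and sessions must have equal length")
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {len(uniq)}")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} must contribute at least 2 calls")
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)

    type_values, types0 = np.unique(types, return_inverse=True)
    k = len(type_values)
    _, session_codes = np.unique(sessions, return_inverse=True)
    member = groups == uniq[0]
    rng = np.random.default_rng(seed)

    def stat(member_vec):
        ca = _group_table_counts(types0, session_codes, member_vec, k)
        cb = _group_table_counts(types0, session_codes, ~member_vec, k)
        return _jsd_similarity(ca, cb)

    nulls = np.empty(n_perm)
    if unit == "transition":
        a = np.arange(len(types) - 1)
        ok = (session_codes[a] == session_codes[a + 1]) & (groups[a] == groups[a + 1])
        cells = types0[a[ok]] * k + types0[a[ok] + 1]
        glab = member[a[ok]]
        observed = _jsd_similarity(
            np.bincount(cells[glab], minlength=k * k).astype(float),
            np.bincount(cells[~glab], minlength=k * k).astype(float),
        )
        for j in range(n_perm):
            gp = rng.permutation(glab)
            nulls[j] = _jsd_similarity(
                np.bincount(cells[gp], minlength=k * k).astype(float),
                np.bincount(cells[~gp], minlength=k * k).astype(float),
            )
    else:
        observed = stat(member)
        if unit == "call":
            for j in range(n_perm):
                nulls[j] = stat(rng.permutation(member))
        elif unit == "block":
            n = len(member)
            starts = np.arange(0, n, block_len)
            blocks = [member[s:s + block_len] for s in starts]
            for j in range(n_perm):
                order = rng.permutation(len(blocks))
                gp = np.concatenate([blocks[i] for i in order])
                nulls[j] = stat(gp)
        else:
            raise ValueError(f"unknown permutation unit {unit!r}")

    p = (np.sum(nulls <= observed) + 1) / (n_perm + 1)
    return NMIResult(
        observed_nmi=float(observed),
        null_nmis=nulls,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        unit=unit,
        alpha=alpha,
        groups=tuple(uniq.tolist()),
    )
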