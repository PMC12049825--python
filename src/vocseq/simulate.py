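"""Synthetic call sequences and series regimes with the statistical
structure the analysis assumes.

The generator emulates the study design the toolkit targets: a small
number of subjects, each recorded over a couple of short sessions
(~30-60 calls), producing calls whose types follow a subject-specific
Markov chain and whose four acoustic parameters are Gaussian emissions
around type-specific means.  Default emission means span the ranges
observed in captive great-ape voiced-call data (>1000 Hz in maxfreq,
>1.5 s in duration, ~12 Hz in freqslope, >2 bits in acoustic entropy
across types); exact values are configuration, not claims about any real
population.

Also provided: simple univariate series regimes (constant, i.i.d.
uniform, fractional ARFIMA noise) used to exercise the entropy and
forecasting stages at their theoretical limits, and two-subject scenarios
with controlled transition-matrix differences for calibration and power
studies of the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import CallRecord, CallSequence
from .forecast import frac_diff_weights


@dataclass
class GeneratorSpec:
    """Study-design parameters of the synthetic call generator.

    Defaults mirror a two-subject, two-session design with 39 calls per
    session (a session length at which an l=8 emergence scan yields 31
    values) and five true call types.
    """

    n_subjects: int = 2
    sessions_per_subject: int = 2
    calls_per_session: int = 39
    k: int = 5
    transition_matrices: np.ndarray | None = None   # (n_subjects, k, k)
    emission_means: np.ndarray | None = None        # (k, 4) parameter order:
    emission_sds: np.ndarray | None = None          # maxfreq, duration, slope, entropy
    noise_scale: float = 1.0
    seed: int = 0

    def resolve(self) -> "GeneratorSpec":
        if self.transition_matrices is None:
            self.transition_matrices = np.stack(
                [default_transition_matrix(self.k, s) for s in range(self.n_subjects)]
            )
        else:
            self.transition_matrices = np.asarray(self.transition_matrices, float)
            rows = self.transition_matrices.sum(axis=-1)
            if not np.allclose(rows, 1.0, atol=1e-8):
                raise ValueError("transition matrix rows must sum to 1")
        if self.emission_means is None:
            self.emission_means = default_emission_means(self.k)
        if self.emission_sds is None:
            self.emission_sds = np.tile(
                np.array([80.0, 0.12, 0.8, 0.25]), (self.k, 1)
            )
        return self


def default_transition_matrix(k: int, subject_index: int = 0) -> np.ndarray:
    """A moderately persistent chain with a subject-specific preferred
    successor: 0.45 self-transition, 0.35 to type (i + 1 + subject) mod k,
    remainder spread uniformly."""
    if k == 1:
        return np.ones((1, 1))
    q = np.zeros((k, k))
    for i in range(k):
        j = (i + 1 + subject_index) % k
        if j == i:
            j = (i + 1) % k
        q[i, i] += 0.45
        q[i, j] += 0.35
        others = [c for c in range(k) if c not in (i, j)]
        if others:
            q[i, others] += 0.20 / len(others)
        else:
            q[i, j] += 0.20
    return q / q.sum(axis=1, keepdims=True)


def default_emission_means(k: int) -> np.ndarray:
    """Type means spread across realistic parameter ranges."""
    return np.column_stack(
        [
            np.linspace(400.0, 1600.0, k),   # maxfreq_hz: span 1200 Hz
            np.linspace(0.3, 2.0, k),        # duration_s: span 1.7 s
            np.linspace(-6.0, 6.0, k),       # freqslope_hz: span 12 Hz
            np.linspace(1.5, 4.0, k),        # entropy_bits: span 2.5 bits
        ]
    )


def _simulate_chain(q: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    k = q.shape[0]
    cum = q.cumsum(axis=1)
    path = np.empty(n, dtype=int)
    path[0] = rng.integers(k)
    u = rng.random(n)
    for t in range(1, n):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def simulate_markov_calls(spec: GeneratorSpec) -> tuple[list[CallSequence], np.ndarray]:
    """Generate call sequences plus the true type path of every call.

    Per session a call-type path is drawn from the subject's Markov chain
    (uniform initial state) and each call's four parameters are Gaussian
    emissions around the type mean.  Duration and maxfreq are truncated
    to stay positive and acoustic entropy to stay nonnegative (simple
    clipping, chosen over rejection sampling for reproducibility).
    Output is deterministic for a fixed seed.
    """
    spec = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    sequences, labels = [], []
    for s in range(spec.n_subjects):
        subject = f"S{s + 1}"
        q = spec.transition_matrices[s]
        for sess in range(spec.sessions_per_subject):
            session = f"sess{sess + 1}"
            path = _simulate_chain(q, spec.calls_per_session, rng)
            records = []
            for order0, typ in enumerate(path):
                mu = spec.emission_means[typ]
                sd = spec.emission_sds[typ] * spec.noise_scale
                draw = rng.normal(mu, sd)
                records.append(
                    CallRecord(
                        subject=subject,
                        session=session,
                        order=order0 + 1,
                        maxfreq=max(float(draw[0]), 1.0),
                        duration=max(float(draw[1]), 0.01),
                        freqslope=float(draw[2]),
                        acentropy=max(float(draw[3]), 0.0),
                    )
                )
            sequences.append(CallSequence(subject, session, records))
            labels.append(path + 1)
    return sequences, np.concatenate(labels)


# ---------------------------------------------------------------------------
# Univariate series regimes
# ---------------------------------------------------------------------------

def simulate_series_regime(
    kind: Literal["constant", "iid_uniform", "arfima"],
    params: dict | None = None,
    n: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Test-harness series at the entropy metrics' theoretical limits.

    * ``constant`` — a single repeated ``value`` (default 0.5): the fully
      deterministic limit, moving emergence identically 0.
    * ``iid_uniform`` — independent draws over [``low``, ``high``]
      (default [0, 1]): the fully random limit.
    * ``arfima`` — fractional noise with memory ``d`` (|d| < 0.5) and
      innovation scale ``sigma``, generated through truncated
      MA(infinity) weights with a burn-in.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "constant":
        return np.full(n, float(params.get("value", 0.5)))
    if kind == "iid_uniform":
        lo, hi = params.get("low", 0.0), params.get("high", 1.0)
        return rng.uniform(lo, hi, n)
    if kind == "arfima":
        if n < 20:
            raise ValueError("arfima regime requires n >= 20")
        d = float(params.get("d", 0.3))
        if abs(d) >= 0.5:
            raise ValueError("|d| must be < 0.5 for a stationary ARFIMA series")
        sigma = float(params.get("sigma", 1.0))
        burn = int(params.get("burn", 500))
        m = n + burn
        # psi_j = psi_{j-1} (j - 1 + d) / j are the (1-B)^{-d} weights
        psi = frac_diff_weights(-d, m)
        eps = rng.normal(0.0, sigma, m)
        x = np.convolve(eps, psi)[:m]
        return x[burn:]
    raise ValueError(f"unknown regime kind {kind!r}")


# ---------------------------------------------------------------------------
# Two-subject scenarios for the permutation test
# ---------------------------------------------------------------------------

#: Base chain of the calibration/power scenarios: moderately persistent,
#: with distinct row structure, so serial dependence is really present.
SCENARIO_BASE_MATRIX = np.array(
    [
        [0.6, 0.3, 0.1],
        [0.1, 0.6, 0.3],
        [0.3, 0.1, 0.6],
    ]
)


def shift_rows_tv(q: np.ndarray, tv: float) -> np.ndarray:
    """A matrix at exact row-wise total-variation distance ``tv`` from
    ``q``, built by moving ``tv`` probability mass per row from its
    largest entries onto its smallest entry."""
    q = np.asarray(q, dtype=float)
    out = q.copy()
    for i, row in enumerate(q):
        recipient = int(np.argmin(row))
        if tv > 1.0 - row[recipient] + 1e-12:
            raise ValueError(f"row {i}: cannot move {tv} mass onto the smallest entry")
        new = row.copy()
        remaining = tv
        for j in np.argsort(-row):
            if j == recipient:
                continue
            take = min(new[j], remaining)
            new[j] -= take
            remaining -= take
            if remaining <= 1e-15:
                break
        new[recipient] += tv
        out[i] = new / new.sum()
    return out


@dataclass
class ScenarioData:
    """Pooled labeled calls ready for the permutation test."""

    types: np.ndarray
    groups: np.ndarray
    sessions: np.ndarray
    matrices: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


TV_BY_DIFFERENCE = {"none": 0.0, "moderate": 0.3, "large": 0.8}


def two_subject_scenario(
    difference: Literal["none", "moderate", "large"] = "none",
    k: int = 3,
    calls_per_subject: int = 60,
    sessions_per_subject: int = 1,
    base_matrix: np.ndarray | None = None,
    seed: int | None = None,
) -> ScenarioData:
    """Two subjects with a controlled transition-structure difference.

    ``none`` gives both subjects the same matrix (type-I calibration);
    ``moderate``/``large`` place the second subject's matrix at row-wise
    total-variation distance 0.3/0.8 from the first's (power studies).
    """
    if base_matrix is None:
        base_matrix = (
            SCENARIO_BASE_MATRIX if k == 3 else default_transition_matrix(k, 0)
        )
    tv = TV_BY_DIFFERENCE[difference]
    q_a = np.asarray(base_matrix, dtype=float)
    q_b = shift_rows_tv(q_a, tv) if tv > 0 else q_a
    rng = np.random.default_rng(seed)
    per_session, rem = divmod(calls_per_subject, sessions_per_subject)
    types, groups, sessions = [], [], []
    for g, q in enumerate((q_a, q_b)):
        for s in range(sessions_per_subject):
            n = per_session + (1 if s < rem else 0)
            types.append(_simulate_chain(q, n, rng) + 1)
            groups.append(np.full(n, g))
            sessions.append(np.full(n, g * sessions_per_subject + s))
    return ScenarioData(
        types=np.concatenate(types),
        groups=np.concatenate(groups),
        sessions=np.concatenate(sessions),
        matrices=(q_a, q_b),
    )


def write_demo_dataset(directory, seed: int = 0) -> dict:
    """Write the bundled demo dataset (calls.csv + true_types.csv)."""
    import pandas as pd
    from pathlib import Path

    from .io import sequences_to_frame, write_call_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = GeneratorSpec(seed=seed)
    seqs, true_types = simulate_markov_calls(spec)
    calls_path = directory / "calls.csv"
    write_call_table(seqs, calls_path)
    truth = sequences_to_frame(seqs)[["subject", "session", "order"]].copy()
    truth["true_type"] = true_types
    types_path = directory / "true_types.csv"
    truth.to_csv(types_path, index=False)
    return {"calls": str(calls_path), "true_types": str(types_path)}
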