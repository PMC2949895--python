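"""Seeded generators: synthetic sequence families and scheduler task costs.

The default protein family emulates a large, highly diverged superfamily:
target mean length 440 residues with lengths spanning [10, 11600] under a
truncated log-normal law (the log-scale sigma is fitted so the *truncated*
mean hits the target).  Members descend from one random ancestor through
point substitutions and geometric-length indels, then are rescaled to
their drawn lengths, so relatives share detectable homology while lengths
stay heavy-tailed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .io_formats import DNA_RESIDUES, PROTEIN_RESIDUES, SequenceRecord, SequenceSet


@dataclass
class FamilyModel:
    """Parameters of a synthetic sequence family."""

    n_sequences: int = 50
    mean_length: float = 440.0
    min_length: int = 10
    max_length: int = 11600
    sigma_log: float = 0.7
    substitution_rate: float = 0.2
    indel_rate: float = 0.05
    indel_extension: float = 0.3  # geometric length parameter p
    alphabet: str = "protein"
    seed: int = 0

    def __post_init__(self):
        if self.min_length > self.max_length:
            raise ValueError(
                f"min_length {self.min_length} exceeds max_length {self.max_length}"
            )
        if not (self.min_length <= self.mean_length <= self.max_length):
            raise ValueError("mean_length must lie within [min_length, max_length]")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        for name in ("substitution_rate", "indel_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.indel_extension <= 1.0:
            raise ValueError("indel_extension must lie in (0, 1]")


def _truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    z = norm.cdf(b) - norm.cdf(a)
    if z <= 0:
        return math.exp(mu + 0.5 * sigma**2)
    return math.exp(mu + 0.5 * sigma**2) * (norm.cdf(b - sigma) - norm.cdf(a - sigma)) / z


def fit_log_mu(mean: float, sigma: float, lo: float, hi: float) -> float:
    """Log-scale location such that the [lo, hi]-truncated log-normal mean
    equals ``mean``."""
    if lo == hi:
        return math.log(lo)

    def f(mu):
        return _truncated_lognormal_mean(mu, sigma, lo, hi) - mean

    span = math.log(hi) - math.log(lo)
    return brentq(f, math.log(lo) - span - 5 * sigma, math.log(hi) + 5 * sigma)


def sample_lengths(model: FamilyModel, rng: np.random.Generator) -> np.ndarray:
    """Draw sequence lengths from the model's truncated log-normal law."""
    lo, hi = float(model.min_length), float(model.max_length)
    if model.sigma_log == 0 or lo == hi:
        return np.full(model.n_sequences, int(round(model.mean_length)), dtype=np.int64)
    mu = fit_log_mu(model.mean_length, model.sigma_log, lo, hi)
    a = (math.log(lo) - mu) / model.sigma_log
    b = (math.log(hi) - mu) / model.sigma_log
    u = rng.uniform(norm.cdf(a), norm.cdf(b), size=model.n_sequences)
    lengths = np.exp(mu + model.sigma_log * norm.ppf(u))
    return np.clip(np.rint(lengths), model.min_length, model.max_length).astype(np.int64)


def _mutate(ancestor: np.ndarray, model: FamilyModel, n_symbols: int,
            rng: np.random.Generator) -> np.ndarray:
    seq = ancestor.copy()
    if model.substitution_rate > 0:
        mask = rng.random(seq.size) < model.substitution_rate
        seq[mask] = rng.integers(0, n_symbols, size=int(mask.sum()))
    if model.indel_rate > 0 and seq.size:
        n_events = rng.poisson(model.indel_rate * seq.size)
        for _ in range(n_events):
            pos = int(rng.integers(0, seq.size + 1))
            length = int(rng.geometric(model.indel_extension))
            if rng.random() < 0.5:  # deletion
                seq = np.delete(seq, slice(pos, pos + length))
            else:  # insertion of random residues
                seq = np.insert(seq, min(pos, seq.size),
                                rng.integers(0, n_symbols, size=length))
    return seq


def gen_family(model: FamilyModel) -> SequenceSet:
    """Generate a seeded synthetic family as a :class:`SequenceSet`."""
    residues = PROTEIN_RESIDUES if model.alphabet == "protein" else DNA_RESIDUES
    n_symbols = len(residues)
    lookup = np.array(list(residues))
    rng = np.random.default_rng(model.seed)
    anc_len = int(np.clip(round(model.mean_length), model.min_length, model.max_length))
    ancestor = rng.integers(0, n_symbols, size=anc_len)
    lengths = sample_lengths(model, rng)
    records: List[SequenceRecord] = []
    digits = max(5, len(str(model.n_sequences)))
    for k in range(model.n_sequences):
        seq = _mutate(ancestor, model, n_symbols, rng)
        target = int(lengths[k])
        if seq.size > target:
            seq = seq[:target]
        elif seq.size < target:
            seq = np.concatenate([seq, rng.integers(0, n_symbols, size=target - seq.size)])
        records.append(SequenceRecord(
            id=f"seq{k:0{digits}d}",
            residues="".join(lookup[seq]),
            description="synthetic family member",
            alphabet=model.alphabet,
        ))
    return SequenceSet(records)


def gen_task_costs(n_tasks: int, distribution: str = "lognormal",
                   seed: int = 0, **params) -> np.ndarray:
    """Seeded non-negative task costs.

    ``uniform(low, high)``; ``lognormal(mean, cv)`` parameterized by its
    arithmetic mean and coefficient of variation; ``pareto(alpha, xm)``
    (alpha > 1 so the mean alpha*xm/(alpha-1) exists).
    """
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        low = float(params.pop("low", 0.5))
        high = float(params.pop("high", 1.5))
        if not 0 <= low <= high:
            raise ValueError(f"need 0 <= low <= high, got ({low}, {high})")
        costs = rng.uniform(low, high, size=n_tasks) if low < high else np.full(n_tasks, low)
    elif distribution == "lognormal":
        mean = float(params.pop("mean", 1.0))
        cv = float(params.pop("cv", 2.0))
        if mean <= 0 or cv <= 0:
            raise ValueError("lognormal needs mean > 0 and cv > 0")
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - 0.5 * sigma2
        costs = rng.lognormal(mu, math.sqrt(sigma2), size=n_tasks)
    elif distribution == "pareto":
        alpha = float(params.pop("alpha", 2.5))
        xm = float(params.pop("xm", 1.0))
        if alpha <= 1 or xm <= 0:
            raise ValueError("pareto needs alpha > 1 (finite mean) and xm > 0")
        costs = xm * (1.0 + rng.pareto(alpha, size=n_tasks))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    if params:
        raise ValueError(f"unexpected parameters: {sorted(params)}")
    return costs
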