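"""Self-contained statistical primitives.

Provides the three tools the rest of the package relies on:

* :func:`rank_sum_test` -- Wilcoxon rank-sum with exact enumeration for small
  untied samples and a tie-corrected normal approximation otherwise.
* :func:`blocked_permutation_test` -- two-group mean contrast in which group
  labels are permuted only within blocks (e.g. parent colony), with exhaustive
  enumeration when the arrangement count is small.
* :func:`adjust_p` -- Holm and Benjamini-Hochberg p-value adjustment.

All Monte Carlo paths take an explicit seed and report it in their result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError

__all__ = [
    "PermutationResult",
    "rank_sum_test",
    "blocked_permutation_test",
    "adjust_p",
]

#: arrangement-count ceiling below which the permutation null is enumerated
EXHAUSTIVE_LIMIT = 20_000

_ABS_TOL = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a (blocked) permutation test.

    ``observed_effect`` is ``mean(group B) - mean(group A)`` where the group
    order is either supplied by the caller or the sorted pair of labels.
    """

    observed_effect: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    n_blocks_used: int = 0
    n_blocks_dropped: int = 0


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_rank_sum_cdf(n: int, m: int) -> np.ndarray:
    """Null probabilities of the rank-sum of the first sample (size ``n``).

    Counts subsets of size ``n`` of the untied ranks ``1..n+m`` by their sum
    via dynamic programming. Entry ``w`` of the returned vector is
    ``P(W = w)``; indices below ``n(n+1)/2`` are zero.
    """
    total = n + m
    max_sum = sum(range(total - n + 1, total + 1))
    ways = np.zeros((n + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(r, n), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r else ways[k - 1, :]
    probs = ways[n] / comb(total, n)
    return probs


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Returns ``(W, p)`` where ``W`` is the rank-sum of ``x`` in the pooled
    mid-ranked sample. The p-value is obtained by exact enumeration when
    ``min(len(x), len(y)) <= 10`` and the pooled sample has no ties, and by a
    tie-corrected, continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires at least one value per group")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if min(n, m) <= 10 and not has_ties:
        probs = _exact_rank_sum_cdf(n, m)
        wi = int(round(w))
        lower = probs[: wi + 1].sum()
        upper = probs[wi:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return w, float(p)

    # normal approximation with mid-rank tie correction
    total = n + m
    mu = n * (total + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (total * (total - 1))
    var = n * m / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mu
    # continuity correction toward the mean
    diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = 2.0 * _sps.norm.sf(abs(z))
    return w, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Blocked permutation
# ---------------------------------------------------------------------------

def _enumerate_block_masks(block_sizes: Sequence[int], block_k: Sequence[int]) -> np.ndarray:
    """All within-block reassignments as a (n_arrangements, n_units) 0/1 matrix.

    Units are ordered block by block; a 1 marks membership of the second
    ("alt") group. Each block contributes every size-``k`` subset of its
    units, and blocks combine as a cross product.
    """
    per_block: list[np.ndarray] = []
    for size, k in zip(block_sizes, block_k):
        rows = np.zeros((comb(size, k), size))
        for i, idx in enumerate(combinations(range(size), k)):
            rows[i, list(idx)] = 1.0
        per_block.append(rows)
    out = per_block[0]
    for rows in per_block[1:]:
        out = np.hstack(
            [np.repeat(out, rows.shape[0], axis=0), np.tile(rows, (out.shape[0], 1))]
        )
    return out


def blocked_permutation_test(
    values: Sequence[float],
    group_labels: Sequence,
    blocks: Sequence,
    n_perm: int = 9999,
    seed: int = 0,
    group_order: tuple | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Permutation test of a two-group mean difference, permuting within blocks.

    The observed effect is ``mean(values[g == alt]) - mean(values[g == ref])``
    with ``(ref, alt) = group_order`` (sorted labels when omitted). Only
    blocks containing at least two units and both groups are permutable;
    others are dropped with a warning. When the total number of within-block
    label arrangements is at most :data:`EXHAUSTIVE_LIMIT` the null is
    enumerated exhaustively (deterministic, seed unused); otherwise ``n_perm``
    Monte Carlo draws are taken and the add-one estimator
    ``p = (1 + #{|perm| >= |obs|}) / (1 + n_perm)`` is used. ``method`` can
    force either route (``"exhaustive"`` raises if the arrangement count
    exceeds the limit).
    """
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ValidationError(f"unknown method {method!r}")
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    blocks = np.asarray(blocks)
    if not (values.shape == group_labels.shape == blocks.shape):
        raise ValidationError("values, group_labels and blocks must be equal length")

    labels = sorted(set(group_labels.tolist()))
    if group_order is not None:
        ref, alt = group_order
        if {ref, alt} != set(labels):
            raise ValidationError(
                f"group_order {group_order!r} does not match labels {labels!r}"
            )
    else:
        if len(labels) != 2:
            raise ValidationError(f"expected exactly two group labels, got {labels!r}")
        ref, alt = labels

    keep = np.zeros(values.size, dtype=bool)
    n_dropped = 0
    for b in np.unique(blocks):
        in_b = blocks == b
        groups_here = set(group_labels[in_b].tolist())
        if in_b.sum() >= 2 and groups_here == {ref, alt}:
            keep |= in_b
        else:
            n_dropped += 1
    if not keep.any():
        raise ValidationError("no block contains units from both groups")
    if n_dropped:
        warnings.warn(
            f"{n_dropped} block(s) lack both groups and were dropped",
            stacklevel=2,
        )

    # order units by block so enumeration/shuffling can act on contiguous runs
    order = np.argsort(blocks[keep], kind="stable")
    v = values[keep][order]
    g = group_labels[keep][order]
    b = blocks[keep][order]

    is_alt = (g == alt).astype(float)
    n_alt = int(is_alt.sum())
    n_ref = v.size - n_alt
    obs = v[is_alt == 1].mean() - v[is_alt == 0].mean()

    uniq, block_start = np.unique(b, return_index=True)
    block_start = np.sort(block_start)
    bounds = list(block_start) + [v.size]
    block_sizes = [bounds[i + 1] - bounds[i] for i in range(len(uniq))]
    block_k = [int(is_alt[bounds[i] : bounds[i + 1]].sum()) for i in range(len(uniq))]

    n_arrangements = 1
    for size, k in zip(block_sizes, block_k):
        n_arrangements *= comb(size, k)
        if n_arrangements > EXHAUSTIVE_LIMIT:
            break

    if method == "exhaustive" and n_arrangements > EXHAUSTIVE_LIMIT:
        raise ValidationError(
            f"exhaustive enumeration requested but > {EXHAUSTIVE_LIMIT} arrangements"
        )
    use_exhaustive = (
        method == "exhaustive"
        or (method == "auto" and n_arrangements <= EXHAUSTIVE_LIMIT)
    )
    if use_exhaustive:
        masks = _enumerate_block_masks(block_sizes, block_k)
        weights = masks / n_alt - (1.0 - masks) / n_ref
        effects = weights @ v
        count = int((np.abs(effects) >= abs(obs) - _ABS_TOL).sum())
        return PermutationResult(
            observed_effect=float(obs),
            p_value=count / masks.shape[0],
            n_permutations=masks.shape[0],
            exhaustive=True,
            seed=None,
            n_blocks_used=len(uniq),
            n_blocks_dropped=n_dropped,
        )

    rng = np.random.default_rng(seed)
    block_id = np.searchsorted(np.sort(block_start), np.arange(v.size), side="right")
    # argsort of (block_id + U) yields an independent permutation within each
    # contiguous block per row
    keys = block_id[None, :] + rng.random((n_perm, v.size))
    idx = np.argsort(keys, axis=1)
    perm_alt = is_alt[idx]
    effects = perm_alt @ v / n_alt - (1.0 - perm_alt) @ v / n_ref
    count = int((np.abs(effects) >= abs(obs) - _ABS_TOL).sum())
    return PermutationResult(
        observed_effect=float(obs),
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        exhaustive=False,
        seed=seed,
        n_blocks_used=len(uniq),
        n_blocks_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

def adjust_p(p_values: Sequence[float], method: str = "BH") -> np.ndarray:
    """Adjust p-values for multiple testing.

    ``method`` is one of ``none``, ``holm`` (step-down) or ``BH``
    (Benjamini-Hochberg step-up). Output is monotone in the input ranks and
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (n - rank) * p[i])
            adj[i] = min(1.0, running)
    elif method == "BH":
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, n * p[i] / (rank + 1))
            adj[i] = min(1.0, running)
    else:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return adj
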