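"""DUPLEX representative splitting into calibration and test subsets.

DUPLEX deterministically assigns the most mutually distant samples to the
two subsets in turn, so that calibration and test both span the data space.
The variant here fills fixed quotas derived from the requested ratio: for a
ratio r:1 the test set receives ``floor(n / (r + 1))`` samples and the
remainder goes to calibration (88 samples at 2:1 -> 59 calibration / 29
test when the two subgroups of 52 and 36 are split independently).

Steps:

1. the two mutually farthest points (Euclidean) open the calibration set;
2. the two farthest remaining points open the test set;
3. thereafter sets alternate (calibration first); each step the remaining
   point with the greatest minimal distance to the receiving set is assigned;
   a set whose quota is filled is skipped.

Ties are broken toward the lowest original row index, which makes the split
deterministic and membership invariant under row permutation whenever the
pairwise distances are distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["DuplexResult", "duplex", "split_modeled_class"]


@dataclass(frozen=True)
class DuplexResult:
    """Calibration/test membership plus the per-step assignment log."""

    calibration: tuple[int, ...]
    test: tuple[int, ...]
    log: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        if set(self.calibration) & set(self.test):
            raise ValueError("calibration and test sets overlap")


def _parse_ratio(ratio) -> tuple[float, float]:
    if isinstance(ratio, str):
        cal, _, test = ratio.partition(":")
        return float(cal), float(test or 1)
    if np.isscalar(ratio):
        return float(ratio), 1.0
    cal, test = ratio
    return float(cal), float(test)


def duplex(X: np.ndarray, ratio=(2, 1)) -> DuplexResult:
    """Split rows of ``X`` into calibration and test sets at ``ratio``.

    ``X`` should already be autoscaled — distances are computed on the same
    matrix the downstream classifier sees.  Fully deterministic given ``X``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("DUPLEX needs at least 2 samples")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    r_cal, r_test = _parse_ratio(ratio)
    if r_cal <= 0 or r_test <= 0:
        raise ValueError("ratio parts must be positive")

    test_quota = int(np.floor(n * r_test / (r_cal + r_test)))
    cal_quota = n - test_quota

    D = squareform(pdist(X))
    remaining = list(range(n))
    cal: list[int] = []
    test: list[int] = []
    log: list[tuple[str, tuple[int, ...]]] = []

    def farthest_pair(idx: list[int]) -> tuple[int, int]:
        best, best_d = (idx[0], idx[1]), -1.0
        for a_pos, a in enumerate(idx):
            for b in idx[a_pos + 1:]:
                d = D[a, b]
                if d > best_d:  # first (lowest-index) pair wins ties
                    best, best_d = (a, b), d
        return best

    def next_point(target: list[int]) -> int:
        best, best_d = remaining[0], -1.0
        for i in remaining:
            d = min(D[i, j] for j in target)
            if d > best_d:
                best, best_d = i, d
        return best

    # Opening pair steps.  The calibration pair precedes the quota check,
    # so n=2 puts both points into calibration (documented degenerate case).
    i, j = farthest_pair(remaining)
    cal += [i, j]
    remaining.remove(i)
    remaining.remove(j)
    log.append(("calibration", (i, j)))
    if remaining and test_quota > 0:
        if len(remaining) >= 2 and test_quota >= 2:
            i, j = farthest_pair(remaining)
            test += [i, j]
            remaining.remove(i)
            remaining.remove(j)
            log.append(("test", (i, j)))
        else:  # room (or points) for only one: take the point farthest from calibration
            i = next_point(cal)
            test.append(i)
            remaining.remove(i)
            log.append(("test", (i,)))

    turn = 0  # 0 -> calibration, 1 -> test
    while remaining:
        if turn == 0 and len(cal) < cal_quota:
            i = next_point(cal)
            cal.append(i)
            remaining.remove(i)
            log.append(("calibration", (i,)))
        elif turn == 1 and len(test) < test_quota:
            i = next_point(test)
            test.append(i)
            remaining.remove(i)
            log.append(("test", (i,)))
        turn = 1 - turn

    return DuplexResult(calibration=tuple(sorted(cal)), test=tuple(sorted(test)), log=tuple(log))


def split_modeled_class(
    X: np.ndarray, labels: Sequence, ratio=(2, 1)
) -> DuplexResult:
    """Run DUPLEX independently per subgroup label and merge the results.

    Healthy volunteers and survivors are split separately so both subsets
    contain both kinds of target-class sample; per-subgroup counts add
    (52 + 36 at 2:1 -> (35 + 24) calibration and (17 + 12) test).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one label per row required")
    cal: list[int] = []
    test: list[int] = []
    log: list[tuple[str, tuple[int, ...]]] = []
    seen = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    for lab in seen:
        rows = np.flatnonzero(labels == lab)
        if rows.size == 0:
            warnings.warn(f"empty subgroup {lab!r}: contributes nothing")
            continue
        if rows.size == 1:
            cal.append(int(rows[0]))
            log.append(("calibration", (int(rows[0]),)))
            continue
        sub = duplex(X[rows], ratio)
        cal += [int(rows[i]) for i in sub.calibration]
        test += [int(rows[i]) for i in sub.test]
        log += [(grp, tuple(int(rows[i]) for i in step)) for grp, step in sub.log]
    return DuplexResult(calibration=tuple(sorted(cal)), test=tuple(sorted(test)), log=tuple(log))
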