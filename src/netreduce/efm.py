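"""Elementary flux mode enumeration — a *validation statistic* only.

Implements the classical tableau algorithm on the split (all-irreversible)
network.  Deliberately restricted to small networks (<= 25 reactions by
default): the package uses it to verify that loss-free compression preserves
the number of elementary modes on toy fixtures, and the benchmark harness
reports it for small reduced models.  It is not a pathway-analysis tool.
"""

from __future__ import annotations

import numpy as np

from .model import MetabolicModel, ModelError

_TOL = 1e-9


def elementary_modes(
    model: MetabolicModel, max_reactions: int = 25
) -> list[np.ndarray]:
    """All elementary flux modes as net flux vectors (one per mode).

    A reversible mode (every support reaction reversible) is returned once,
    in a canonical orientation.  Bounds are used only for reversibility
    (lower bound < 0); magnitudes are normalised to max |v| = 1.
    """
    n = model.n_reactions
    if n > max_reactions:
        raise ModelError(
            f"elementary-mode enumeration is restricted to <= {max_reactions} "
            f"reactions (got {n}); it is a validation statistic, not a tool"
        )
    rev = model.lower_bounds < 0
    split: list[tuple[int, int]] = [(j, +1) for j in range(n)]
    split += [(int(j), -1) for j in np.nonzero(rev)[0]]
    ns = len(split)
    m = model.n_metabolites
    N = np.zeros((m, ns))
    for k, (j, s) in enumerate(split):
        N[:, k] = s * model.S[:, j]

    # tableau rows: (flux over split reactions, residual imbalance per metabolite)
    fluxes = [np.eye(ns)[k] for k in range(ns)]
    residuals = [N[:, k].copy() for k in range(ns)]

    for i in range(m):
        keep_f, keep_r, pos, neg = [], [], [], []
        for f, r in zip(fluxes, residuals):
            if abs(r[i]) <= _TOL:
                keep_f.append(f)
                keep_r.append(r)
            elif r[i] > 0:
                pos.append((f, r))
            else:
                neg.append((f, r))
        for fp, rp in pos:
            for fq, rq in neg:
                l1, l2 = -rq[i], rp[i]
                f = l1 * fp + l2 * fq
                r = l1 * rp + l2 * rq
                scale = np.abs(f).max()
                if scale <= _TOL:
                    continue
                f /= scale
                r /= scale
                f[np.abs(f) <= _TOL] = 0.0
                r[np.abs(r) <= _TOL] = 0.0
                keep_f.append(f)
                keep_r.append(r)
        # minimality: drop rows whose support strictly contains another's
        supports = [frozenset(np.nonzero(f > _TOL)[0]) for f in keep_f]
        minimal = []
        for a, sa in enumerate(supports):
            if any(
                b != a and supports[b] < sa for b in range(len(supports))
            ) or any(
                b < a and supports[b] == sa for b in range(len(supports))
            ):
                continue
            minimal.append(a)
        fluxes = [keep_f[a] for a in minimal]
        residuals = [keep_r[a] for a in minimal]

    # map split fluxes back to net vectors; drop the spurious forward+backward
    # two-cycles created by splitting a reversible reaction
    modes: list[np.ndarray] = []
    seen: set[tuple] = set()
    pair_of = {}
    for k, (j, s) in enumerate(split):
        if s == -1:
            fwd = split.index((j, +1))
            pair_of[frozenset((fwd, k))] = j
    for f in fluxes:
        support = frozenset(np.nonzero(f > _TOL)[0])
        if support in pair_of:
            continue
        v = np.zeros(n)
        for k, (j, s) in enumerate(split):
            v[j] += s * f[k]
        v[np.abs(v) <= _TOL] = 0.0
        if not np.any(v):
            continue
        scale = np.abs(v).max()
        v /= scale
        # canonical orientation: first nonzero entry positive
        first = np.nonzero(v)[0][0]
        if v[first] < 0:
            v = -v
        key = tuple(np.round(v, 9))
        if key not in seen:
            seen.add(key)
            modes.append(v)
    return modes


def count_efms(model: MetabolicModel, max_reactions: int = 25) -> int:
    """Number of elementary flux modes (see :func:`elementary_modes`)."""
    return len(elementary_modes(model, max_reactions))
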