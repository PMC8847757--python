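"""Pure, deterministic kernels of the model: resource production, sharing,
reproduction and survival.

These four functions are the whole biology of the model; everything else in
the package (the stochastic engine, experiments, analysis) is plumbing around
them.  All functions are stateless, accept scalars or numpy arrays, and raise
:class:`~coopdyn.exceptions.InvalidParameterError` on out-of-domain input.

Model summary
-------------
A group of individuals shares a resource pool.  The pool equals the
environmental baseline ``R0`` plus a saturating (Monod-type) increment earned
by the summed cooperation degree of the group's members:

    R_group = R0 * (1 + I * bK * sum_phi / (I * R0 / 2 + bK * sum_phi))

so a group with no cooperative benefit gets exactly ``R0``, and no group can
exceed ``R0 * (1 + I)``.  Members split ``R_group`` equally; the per-capita
share ``s`` fuels reproduction through a second Monod term on the surplus
``s - M`` above metabolic consumption, discounted by the cooperation cost
``(1 - beta * phi)``:

    F = alpha * (1 - beta * phi) * (s - M) / (Ks + (s - M))    for s > M,

and ``F = 0`` when ``s <= M`` (starvation halts reproduction but does not
directly kill; mortality is purely age-dependent).  Survival each step is

    r = c * exp(-age / age_standard).
"""

from __future__ import annotations

import numpy as np

from .exceptions import EmptyGroupError, InvalidParameterError

__all__ = [
    "group_resource",
    "per_capita_share",
    "reproductive_rate",
    "survival_probability",
]


def group_resource(R0_t, I, bK, sum_phi):
    """Resources available to a group, given its total cooperation degree.

    Parameters
    ----------
    R0_t : float or ndarray
        Environmental resource availability at this step (must be > 0).
    I : float
        Maximum resource increment rate (> 0).
    bK : float
        Cooperation efficiency (>= 0).
    sum_phi : float or ndarray
        Summed cooperation degree of the group's members (>= 0).

    Returns
    -------
    float or ndarray
        Group resources in ``[R0_t, R0_t * (1 + I))``.  Exactly ``R0_t``
        when the cooperative benefit ``bK * sum_phi`` is zero.
    """
    R0_t = np.asarray(R0_t, dtype=float)
    sum_phi = np.asarray(sum_phi, dtype=float)
    if np.any(R0_t <= 0):
        raise InvalidParameterError("R0_t must be positive")
    if I <= 0:
        raise InvalidParameterError("I must be positive")
    if bK < 0:
        raise InvalidParameterError("bK must be non-negative")
    if np.any(sum_phi < 0):
        raise InvalidParameterError("sum_phi must be non-negative")
    benefit = bK * sum_phi
    # np.where evaluates both branches; the benefit==0 branch divides by a
    # strictly positive denominator, so no warning suppression is needed.
    out = R0_t * (1.0 + I * benefit / (I * R0_t / 2.0 + benefit))
    out = np.where(benefit > 0, out, R0_t)
    return out if out.ndim else float(out)


def per_capita_share(R_group, N_group):
    """Equal share of the group resources: ``R_group / N_group``.

    Raises
    ------
    EmptyGroupError
        If ``N_group`` is zero; callers must skip empty groups.
    """
    N_group = np.asarray(N_group)
    R_group = np.asarray(R_group, dtype=float)
    if np.any(N_group == 0):
        raise EmptyGroupError("per-capita share undefined for an empty group")
    if np.any(N_group < 0) or np.any(R_group < 0):
        raise InvalidParameterError("R_group and N_group must be non-negative")
    out = R_group / N_group
    return out if out.ndim else float(out)


def reproductive_rate(alpha, beta, phi, s, M, Ks):
    """Expected offspring of one individual this step.

    A saturating (Monod) function of the resource surplus ``s - M``,
    discounted by the cooperation cost ``1 - beta * phi``; clamped to 0
    when the share does not cover metabolism (``s <= M``).

    Returns
    -------
    float or ndarray
        Rate in ``[0, alpha]``; non-decreasing in ``s``, non-increasing
        in ``phi`` and ``beta``.
    """
    phi = np.asarray(phi, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise InvalidParameterError("phi must lie in [0, 1]")
    if not 0.0 < beta <= 1.0:
        raise InvalidParameterError("beta must be in (0, 1]")
    if alpha <= 0 or Ks <= 0 or M < 0:
        raise InvalidParameterError("require alpha > 0, Ks > 0, M >= 0")
    if np.any(s < 0):
        raise InvalidParameterError("s must be non-negative")
    surplus = s - M
    safe = np.where(surplus > 0, surplus, 0.0)
    out = alpha * (1.0 - beta * phi) * safe / (Ks + safe)
    return out if out.ndim else float(out)


def survival_probability(c, age, age_standard):
    """Per-step survival probability: ``c * exp(-age / age_standard)``.

    Equals ``c`` for a newborn (age 0) and decays with an e-folding scale
    of ``age_standard`` steps; always in ``(0, c]``.
    """
    age = np.asarray(age, dtype=float)
    if not 0.0 < c <= 1.0:
        raise InvalidParameterError("c must be in (0, 1]")
    if age_standard <= 0:
        raise InvalidParameterError("age_standard must be positive")
    if np.any(age < 0):
        raise InvalidParameterError("age must be non-negative")
    out = c * np.exp(-age / age_standard)
    return out if out.ndim else float(out)
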