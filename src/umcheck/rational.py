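"""Exact rational polyhedral-cone enumeration.

The analyses that must be exact — conserved-moiety detection and the
brute-force flux-mode oracle — both reduce to enumerating the extreme
rays of a pointed cone ``{x >= 0 : A @ x = 0}`` with rational ``A``.
This module implements the incremental double-description method in
:class:`fractions.Fraction` arithmetic: start from the nonnegative
orthant's rays (unit vectors) and intersect with one hyperplane at a
time, combining adjacent positive/negative rays.  Adjacency uses the
standard combinatorial test (no third ray's support fits inside the
union of the pair's supports), which keeps the intermediate ray count
near-minimal.

Intended for small systems (tens of columns); genome-scale inputs should
be column-scoped first.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Sequence

import sympy

__all__ = ["extreme_rays", "rational_nullspace", "RayLimitExceeded"]


class RayLimitExceeded(RuntimeError):
    """Enumeration produced more rays than the configured cap."""


def _normalize(ray: Sequence[Fraction]) -> tuple[Fraction, ...]:
    """Scale to coprime integer entries (unique representative)."""
    denom_lcm = 1
    for value in ray:
        if value != 0:
            denom_lcm = denom_lcm * value.denominator // gcd(
                denom_lcm, value.denominator
            )
    ints = [int(value * denom_lcm) for value in ray]
    g = 0
    for value in ints:
        g = gcd(g, abs(value))
    if g == 0:
        return tuple(Fraction(0) for _ in ray)
    return tuple(Fraction(value, g) for value in ints)


def extreme_rays(
    matrix: Sequence[Sequence[Fraction]],
    max_rays: int | None = None,
) -> list[tuple[Fraction, ...]]:
    """Extreme rays of ``{x >= 0 : matrix @ x = 0}``.

    Returns normalized (coprime-integer) rays; the zero cone yields an
    empty list.  Raises :class:`RayLimitExceeded` when the working set
    grows past *max_rays*.
    """
    if not matrix:
        raise ValueError("matrix must have at least one row")
    n_cols = len(matrix[0])
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(1) if j == i else Fraction(0) for j in range(n_cols))
        for i in range(n_cols)
    ]
    for row in matrix:
        row = [Fraction(x) for x in row]
        if all(x == 0 for x in row):
            continue
        scores = [sum(a * r for a, r in zip(row, ray)) for ray in rays]
        zeros = [ray for ray, s in zip(rays, scores) if s == 0]
        plus = [(ray, s) for ray, s in zip(rays, scores) if s > 0]
        minus = [(ray, s) for ray, s in zip(rays, scores) if s < 0]
        supports = {ray: frozenset(j for j, v in enumerate(ray) if v != 0)
                    for ray in rays}
        new_rays: list[tuple[Fraction, ...]] = []
        seen: set[tuple[Fraction, ...]] = set()
        for ray_p, s_p in plus:
            for ray_m, s_m in minus:
                union = supports[ray_p] | supports[ray_m]
                adjacent = True
                for other in rays:
                    if other is ray_p or other is ray_m:
                        continue
                    if supports[other] <= union:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = tuple(
                    s_p * vm - s_m * vp for vp, vm in zip(ray_p, ray_m)
                )
                norm = _normalize(combo)
                if any(v != 0 for v in norm) and norm not in seen:
                    seen.add(norm)
                    new_rays.append(norm)
        rays = []
        seen_all: set[tuple[Fraction, ...]] = set()
        for ray in zeros + new_rays:
            norm = _normalize(ray)
            if norm not in seen_all and any(v != 0 for v in norm):
                seen_all.add(norm)
                rays.append(norm)
        if max_rays is not None and len(rays) > max_rays:
            raise RayLimitExceeded(
                f"double description produced {len(rays)} rays (cap {max_rays})"
            )
    return rays


def rational_nullspace(
    matrix: Sequence[Sequence[Fraction]],
) -> list[tuple[Fraction, ...]]:
    """Exact basis of ``{x : matrix @ x = 0}`` (no sign constraint)."""
    if not matrix:
        raise ValueError("matrix must have at least one row")
    m = sympy.Matrix([[sympy.Rational(x) for x in row] for row in matrix])
    basis = m.nullspace()
    out = []
    for vec in basis:
        out.append(_normalize([Fraction(int(v.p), int(v.q)) for v in vec]))
    return out
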