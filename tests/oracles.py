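"""Independent brute-force oracles used by the test suite.

Exact rational-arithmetic enumeration of conditional table probabilities
(Fisher / Freeman-Halton) and a hand product-limit survival calculation.
These deliberately share no code with the package implementations.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = [list(map(int, row)) for row in table]
    r0, r1 = a + b, c + d
    c0 = a + c
    n = r0 + r1
    if r0 == 0 or r1 == 0 or c0 == 0 or (b + d) == 0:
        return 1.0
    denom = comb(n, c0)

    def prob(x: int) -> Fraction | None:
        if x < 0 or x > r0 or c0 - x < 0 or c0 - x > r1:
            return None
        return Fraction(comb(r0, x) * comb(r1, c0 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r0, c0) + 1):
        p = prob(x)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


def fisher_2x3_oracle(table) -> float:
    """Two-sided Freeman-Halton p by exact rational enumeration."""
    (a, b, c), (d, e, f) = [list(map(int, row)) for row in table]
    r0, r1 = a + b + c, d + e + f
    cols = [a + d, b + e, c + f]
    n = r0 + r1
    if r0 == 0 or r1 == 0:
        return 1.0
    base = Fraction(
        factorial(r0) * factorial(r1)
        * factorial(cols[0]) * factorial(cols[1]) * factorial(cols[2]),
        factorial(n),
    )

    def prob(x: int, y: int) -> Fraction | None:
        z = r0 - x - y
        cells = (x, y, z, cols[0] - x, cols[1] - y, cols[2] - z)
        if min(cells) < 0:
            return None
        out = base
        for cell in cells:
            out /= factorial(cell)
        return out

    p_obs = prob(a, b)
    total = Fraction(0)
    for x in range(r0 + 1):
        for y in range(r0 - x + 1):
            p = prob(x, y)
            if p is not None and p <= p_obs:
                total += p
    return float(total)


def fisher_2x3_all_probs(row_margins, col_margins) -> list[Fraction]:
    """Conditional probabilities of every 2x3 table with the given margins."""
    r0, r1 = row_margins
    cols = list(col_margins)
    n = r0 + r1
    base = Fraction(
        factorial(r0) * factorial(r1)
        * factorial(cols[0]) * factorial(cols[1]) * factorial(cols[2]),
        factorial(n),
    )
    out = []
    for x in range(r0 + 1):
        for y in range(r0 - x + 1):
            z = r0 - x - y
            cells = (x, y, z, cols[0] - x, cols[1] - y, cols[2] - z)
            if min(cells) < 0:
                continue
            p = base
            for cell in cells:
                p /= factorial(cell)
            out.append(p)
    return out


def km_by_hand(times, events) -> dict[float, float]:
    """Product-limit estimate as an explicit loop over sorted event times."""
    pairs = sorted(zip(map(float, times), map(int, events)))
    n = len(pairs)
    surv = 1.0
    out: dict[float, float] = {}
    i = 0
    while i < n:
        t = pairs[i][0]
        at = [e for (tt, e) in pairs if tt == t]
        d = sum(at)
        n_risk = sum(1 for (tt, _) in pairs if tt >= t)
        if d:
            surv *= 1 - d / n_risk
        out[t] = surv
        i += len(at)
    return out
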