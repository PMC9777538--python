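"""Independent brute-force re-implementations used as test oracles.

Deliberately written as plain loops over the rule base, sharing no code with
the layered implementation they check.
"""

from __future__ import annotations

INPUT_ORDER = ("ntprobnp", "na", "k")


def trap(x: float, a: float, b: float, c: float, d: float) -> float:
    if b <= x <= c:
        return 1.0
    if a < x < b:
        return (x - a) / (b - a)
    if c < x < d:
        return (d - x) / (d - c)
    return 0.0


def rule_strength(x, model, rule) -> float:
    degrees = []
    for pos, var in enumerate(INPUT_ORDER):
        mf = model.input_mfs[var][rule.antecedent[pos] - 1]
        degrees.append(trap(x[pos], mf.a, mf.b, mf.c, mf.d))
    if model.tnorm == "product":
        return degrees[0] * degrees[1] * degrees[2]
    return min(degrees)


def rule_value(x, rule) -> float:
    v = sum(c * xi for c, xi in zip(rule.coefficients, x))
    return v + rule.bias if rule.bias is not None else v


def weighted_average_output(x, model) -> float:
    """Single-expression forward pass: sum(w * V) / sum(w)."""
    num = 0.0
    den = 0.0
    for rule in model.rules:
        w = rule_strength(x, model, rule)
        num += w * rule_value(x, rule)
        den += w
    return num / den


def consequent_features(x_rows, model) -> list[list[float]]:
    """Design matrix of the consequent least-squares subproblem, row by row."""
    rows = []
    for x in x_rows:
        strengths = [rule_strength(x, model, r) for r in model.rules]
        total = sum(strengths)
        row = []
        for w in strengths:
            for xi in x:
                row.append((w / total) * xi)
        rows.append(row)
    return rows
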