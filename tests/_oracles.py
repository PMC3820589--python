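"""Independent brute-force oracles used by several test modules.

These are straight transcriptions of the declared rules, kept free of any
code path they are used to check.
"""

from fractions import Fraction


def brute_force_keep(site, min_minor_count, min_coverage, max_coverage):
    """Literal transcription of the three SNP-identification rules.

    Rule 1: every pool's four-nucleotide coverage within bounds.
    Rule 2: at least two nucleotides present in the combined counts.
    Rule 3: the second most frequent nucleotide (combined across pools,
    ties broken A < C < G < T) reaches the minimum minor count.
    """
    bases = "ATCG"  # sync column order
    pools = [list(map(int, row)) for row in site.counts]
    for row in pools:
        cov = row[0] + row[1] + row[2] + row[3]
        if cov < min_coverage or cov > max_coverage:
            return False
    combined = {b: sum(row[i] for row in pools) for i, b in enumerate(bases)}
    present = [b for b in combined if combined[b] > 0]
    if len(present) < 2:
        return False
    ranked = sorted("ACGT", key=lambda b: (-combined[b], b))
    return combined[ranked[1]] >= min_minor_count


def ols_closed_form(xs, ys):
    """Normal-equation OLS with exact rational arithmetic.

    Returns (slope, intercept, r_squared) as Fractions.
    """
    xs = [Fraction(x).limit_denominator(10**9) for x in xs]
    ys = [Fraction(y).limit_denominator(10**9) for y in ys]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    syy = sum(y * y for y in ys)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    sxx_c = sxx - sx * sx / n
    syy_c = syy - sy * sy / n
    sxy_c = sxy - sx * sy / n
    r_squared = sxy_c * sxy_c / (sxx_c * syy_c)
    return slope, intercept, r_squared
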