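"""Independent brute-force oracles used to pin expected values.

These deliberately use different computational routes than the package:
the Fisher oracle enumerates every table with the observed margins and
computes each table's probability from the factorial formula with exact
rational arithmetic; the window oracle enumerates every substring of every
length and keeps those covering the mutated residue.
"""

from fractions import Fraction
from math import factorial


def fisher_greater_oracle(ta: int, tr: int, na: int, nr: int) -> float:
    """One-sided (tumor alt enrichment) Fisher p by full table enumeration."""
    n1, n2 = ta + tr, na + nr
    k_alt = ta + na
    total = n1 + n2
    denom_margins = (
        factorial(n1) * factorial(n2) * factorial(k_alt) * factorial(total - k_alt)
    )
    p = Fraction(0)
    for k in range(0, min(k_alt, n1) + 1):
        # table (k, n1-k, k_alt-k, n2-(k_alt-k)) with the same margins
        na_k = k_alt - k
        if n1 - k < 0 or na_k < 0 or n2 - na_k < 0:
            continue
        if k >= ta:
            prob = Fraction(
                denom_margins,
                factorial(total)
                * factorial(k)
                * factorial(n1 - k)
                * factorial(na_k)
                * factorial(n2 - na_k),
            )
            p += prob
    return float(p)


def window_oracle(protein_mut: str, protein_wt: str, position: int, lengths) -> list:
    """All (mut_peptide, wt_peptide, offset) windows covering ``position``."""
    n = len(protein_wt)
    out = []
    for L in sorted(set(lengths)):
        for start in range(1, n - L + 2):
            if start <= position <= start + L - 1:
                out.append(
                    (
                        protein_mut[start - 1: start - 1 + L],
                        protein_wt[start - 1: start - 1 + L],
                        position - start + 1,
                    )
                )
    return out


def window_count_closed_form(n: int, p: int, lengths) -> int:
    """Closed form: sum over L of max(0, min(p, n-L+1) - max(1, p-L+1) + 1)."""
    return sum(
        max(0, min(p, n - L + 1) - max(1, p - L + 1) + 1) for L in sorted(set(lengths))
    )
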