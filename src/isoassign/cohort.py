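"""Two-sample t statistics recomputed from printed group summaries.

Published comparisons of hatch-year (European-grown) versus adult
(African-grown) feathers report only group means, SDs and ns; these
utilities recompute the t statistics from exactly that information, with
both the pooled-variance and the Welch (Satterthwaite) variants.
"""

from __future__ import annotations

import dataclasses

__all__ = ["GroupSummary", "pooled_t_from_summary", "welch_t_from_summary"]


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean ± sd (‰) and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int]:
    """Pooled-variance two-sample |t| and its degrees of freedom.

    t = (x̄_a − x̄_b) / (s_p √(1/n_a + 1/n_b)) with
    s_p² = [(n_a−1)s_a² + (n_b−1)s_b²] / (n_a + n_b − 2); df = n_a + n_b − 2.
    Reported as |t| to match the sign convention of printed tables.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero; t undefined")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    t = (a.mean - b.mean) / (sp2 ** 0.5 * (1 / a.n + 1 / b.n) ** 0.5)
    return abs(t), df


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Welch |t| and Satterthwaite df (no equal-variance assumption)."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both group SDs are zero; t undefined")
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    t = (a.mean - b.mean) / (va + vb) ** 0.5
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return abs(t), df
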