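"""Two-way repeated-measures ANOVA for the Observed/Random x Topic/Comment contrasts.

Every group-level contrast in the pipeline is a fully within-subject
two-factor design: each dyad contributes one cell mean per condition
(e.g. observed-topic, observed-comment, random-topic, random-comment).
The decomposition is the standard within-subject one — each effect is
tested against its own subject-by-effect interaction mean square — with
no sphericity correction (for two-level factors sphericity is trivially
satisfied; for the four-level quartile factor the uncorrected F is
reported and documented as such).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_EPS = 1e-12


@dataclass(frozen=True)
class AnovaResult:
    """One effect of a within-subject two-way ANOVA."""

    effect: str
    F: float
    df1: int
    df2: int
    p: float

    def __str__(self) -> str:  # mirrors the conventional F(df1, df2) report
        return f"{self.effect}: F({self.df1}, {self.df2}) = {self.F:.2f}, p = {self.p:.4g}"


def _f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    if df_err <= 0:
        raise ValueError("need at least 2 subjects for a within-subject ANOVA")
    if ss_eff < _EPS:
        return 0.0, 1.0
    if ss_err < _EPS:
        return float("inf"), 0.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(stats.f.sf(F, df_eff, df_err))


def rm_anova_two_way(
    values: np.ndarray,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
) -> list[AnovaResult]:
    """Within-subject two-way ANOVA on an (n_subjects, a, b) cell-mean array.

    Returns the two main effects and their interaction, each tested
    against its subject-by-effect error term.  Cells must be complete;
    missing (NaN) cells raise.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3:
        raise ValueError("values must be (n_subjects, a_levels, b_levels)")
    if np.isnan(Y).any():
        raise ValueError("missing cells: the design must be complete for every subject")
    n, a, b = Y.shape
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")
    g = Y.mean()
    mS = Y.mean(axis=(1, 2))
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    mAB = Y.mean(axis=0)

    ss_A = n * b * np.sum((mA - g) ** 2)
    ss_SA = b * np.sum((mSA - mS[:, None] - mA[None, :] + g) ** 2)
    ss_B = n * a * np.sum((mB - g) ** 2)
    ss_SB = a * np.sum((mSB - mS[:, None] - mB[None, :] + g) ** 2)
    ss_AB = n * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    resid = (
        Y
        - mSA[:, :, None]
        - mSB[:, None, :]
        - mAB[None, :, :]
        + mS[:, None, None]
        + mA[None, :, None]
        + mB[None, None, :]
        - g
    )
    ss_SAB = np.sum(resid**2)

    specs = [
        (factor_names[0], ss_A, a - 1, ss_SA, (a - 1) * (n - 1)),
        (factor_names[1], ss_B, b - 1, ss_SB, (b - 1) * (n - 1)),
        ("interaction", ss_AB, (a - 1) * (b - 1), ss_SAB, (a - 1) * (b - 1) * (n - 1)),
    ]
    out = []
    for effect, ss_eff, df_eff, ss_err, df_err in specs:
        F, p = _f_and_p(ss_eff, df_eff, ss_err, df_err)
        out.append(AnovaResult(effect=effect, F=F, df1=df_eff, df2=df_err, p=p))
    return out


def rm_anova_2x2(
    values: np.ndarray,
    factor_names: tuple[str, str] = ("network_type", "node_category"),
) -> list[AnovaResult]:
    """The pipeline's standard 2x2 within-subject contrast.

    ``values`` is (n_dyads, 2, 2); with two-level factors every effect
    has df1 = 1 and df2 = n_dyads - 1.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise ValueError("values must be (n_subjects, 2, 2)")
    return rm_anova_two_way(Y, factor_names)
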