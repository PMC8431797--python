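"""External-validation statistics and decoy-set enrichment scores.

External predictivity of a QSAR model on a held-out test set is judged by
the Golbraikh–Tropsha / Roy statistic suite: squared Pearson correlation
r², through-origin regression slopes k and k′ with their determination
coefficients r₀² and r₀′², Roy's penalized r_m² pair

    r_m²  = r²·(1 − √(r² − r₀²)),    r_m′² = r²·(1 − √(r² − r₀′²)),

their absolute difference Δr_m² and mean, the predictive r_pred² relative
to the training-set mean activity, and the test-set RMSE.  The slope and
r₀² conventions are genuinely ambiguous in the literature; this package
fixes the pair that reproduces the reference worked example:

    k  = Σyŷ / Σŷ²  with  r₀²  = 1 − Σ(y − k·ŷ)²/Σ(y − ȳ)²,
    k′ = Σyŷ / Σy²  with  r₀′² = 1 − Σ(ŷ − k′·y)²/Σ(ŷ − ȳ̂)²,

where y is observed and ŷ predicted.  A negative r_m² radicand (possible
on degenerate inputs where r₀² > r²) is floored at zero.

Pharmacophore screens against a decoy database are summarized by the
enrichment factor EF = (Ha/Ht)/(A/D) and the Güner–Henry score

    GH = [Ha·(3A + Ht)/(4·Ht·A)] · [1 − (Ht − Ha)/(D − A)],

with Ha the retrieved actives, Ht all hits, A the actives in the database
and D its total size.  A usable model satisfies EF > 1 and 0.6 < GH < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DomainError

GATE_RPRED_MIN = 0.6
GATE_K_RANGE = (0.85, 1.15)
GATE_DELTA_RM2_MAX = 0.2
GATE_RM2_MEAN_MIN = 0.5
GATE_R0_RATIO_MAX = 0.1


@dataclass
class ValidationReport:
    rmse: float
    r2: float
    r0_2: float
    r0p_2: float
    k: float
    k_prime: float
    rm2: float
    rm2_prime: float
    delta_rm2: float
    rm2_mean: float
    r_pred2: float
    passed: bool
    reasons: list[str]

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in
                ("rmse", "r2", "r0_2", "r0p_2", "k", "k_prime", "rm2",
                 "rm2_prime", "delta_rm2", "rm2_mean", "r_pred2", "passed")}


def _rm2(r2: float, r0: float) -> float:
    return r2 * (1.0 - np.sqrt(max(r2 - r0, 0.0)))


def external_validation(actual, predicted, train_mean: float) -> ValidationReport:
    """Full external statistic suite with the conventional pass/fail gate."""
    y = np.asarray(actual, float).ravel()
    yh = np.asarray(predicted, float).ravel()
    if y.size != yh.size or y.size == 0:
        raise DomainError("actual and predicted must have equal non-zero length")
    if not np.isfinite(train_mean):
        raise DomainError("train_mean must be finite")
    if np.std(y) < 1e-12:
        raise DegenerateInputError("zero-variance observed activities")
    if np.sum(y * y) < 1e-12 or np.sum(yh * yh) < 1e-12:
        raise DegenerateInputError("through-origin slopes undefined on all-zero data")
    rmse = float(np.sqrt(np.mean((yh - y) ** 2)))
    r2 = float(np.corrcoef(y, yh)[0, 1] ** 2)
    k = float(np.sum(y * yh) / np.sum(yh * yh))
    k_prime = float(np.sum(y * yh) / np.sum(y * y))
    r0_2 = float(1.0 - np.sum((y - k * yh) ** 2) / np.sum((y - y.mean()) ** 2))
    r0p_2 = float(1.0 - np.sum((yh - k_prime * y) ** 2) / np.sum((yh - yh.mean()) ** 2))
    rm2 = float(_rm2(r2, r0_2))
    rm2_prime = float(_rm2(r2, r0p_2))
    delta = abs(rm2 - rm2_prime)
    mean = 0.5 * (rm2 + rm2_prime)
    r_pred2 = float(1.0 - np.sum((yh - y) ** 2) / np.sum((y - train_mean) ** 2))
    reasons = []
    if not r_pred2 > GATE_RPRED_MIN:
        reasons.append(f"r_pred2 {r_pred2:.3f} fails > {GATE_RPRED_MIN}")
    k_ok = GATE_K_RANGE[0] < k < GATE_K_RANGE[1]
    kp_ok = GATE_K_RANGE[0] < k_prime < GATE_K_RANGE[1]
    if not (k_ok or kp_ok):
        reasons.append(f"neither k {k:.3f} nor k' {k_prime:.3f} in {GATE_K_RANGE}")
    if not delta < GATE_DELTA_RM2_MAX:
        reasons.append(f"delta rm2 {delta:.3f} fails < {GATE_DELTA_RM2_MAX}")
    if not mean > GATE_RM2_MEAN_MIN:
        reasons.append(f"mean rm2 {mean:.3f} fails > {GATE_RM2_MEAN_MIN}")
    ratio_ok = ((r2 - r0_2) / r2 < GATE_R0_RATIO_MAX
                or (r2 - r0p_2) / r2 < GATE_R0_RATIO_MAX)
    if not ratio_ok:
        reasons.append("(r2 - r0^2)/r2 exceeds 0.1 for both slope conventions")
    return ValidationReport(rmse=rmse, r2=r2, r0_2=r0_2, r0p_2=r0p_2, k=k,
                            k_prime=k_prime, rm2=rm2, rm2_prime=rm2_prime,
                            delta_rm2=delta, rm2_mean=mean, r_pred2=r_pred2,
                            passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    ha: int
    ht: int
    a: int
    d: int
    ef: float
    gh: float

    @classmethod
    def from_counts(cls, ha: int, ht: int, a: int, d: int) -> "EnrichmentResult":
        return cls(ha=ha, ht=ht, a=a, d=d,
                   ef=enrichment_factor(ha, ht, a, d),
                   gh=gh_score(ha, ht, a, d))


def _check_counts(ha: int, ht: int, a: int, d: int) -> None:
    if ht == 0 or a == 0 or d == 0:
        raise DomainError("Ht, A and D must all be positive")
    if not (0 <= ha <= min(ht, a)):
        raise DomainError(f"need 0 <= Ha <= min(Ht, A), got Ha={ha} Ht={ht} A={a}")
    if ht > d:
        raise DomainError(f"hit list Ht={ht} larger than database D={d}")


def enrichment_factor(ha: int, ht: int, a: int, d: int) -> float:
    """EF = (Ha/Ht)/(A/D); zero when no active was retrieved."""
    _check_counts(ha, ht, a, d)
    if ha == 0:
        return 0.0
    return (ha / ht) / (a / d)


def gh_score(ha: int, ht: int, a: int, d: int) -> float:
    """Güner–Henry goodness-of-hit: yield/recall mix with a false-positive penalty."""
    _check_counts(ha, ht, a, d)
    if d <= a:
        raise DomainError("decoy database must be larger than its active subset")
    return (ha * (3 * a + ht) / (4.0 * ht * a)) * (1.0 - (ht - ha) / (d - a))


def find_enrichment_counts(ef_target: float, gh_target: float, a: int, d: int,
                           max_ht: int = 200) -> tuple[int, int, float, float]:
    """Exhaustive integer search for the (Ha, Ht) pair whose EF and GH lie
    closest to given targets; returns (ha, ht, ef, gh).

    Used to reverse-engineer hit counts from published enrichment scores.
    """
    best = None
    for ht in range(1, max_ht + 1):
        for ha in range(0, min(ht, a) + 1):
            ef = enrichment_factor(ha, ht, a, d)
            gh = gh_score(ha, ht, a, d)
            score = max(abs(ef - ef_target) / max(abs(ef_target), 1.0),
                        abs(gh - gh_target))
            if best is None or score < best[0]:
                best = (score, ha, ht, ef, gh)
    _, ha, ht, ef, gh = best
    return ha, ht, ef, gh
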