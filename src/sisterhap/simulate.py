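"""Synthetic case/control haplotype tables from a three-locus crossover model.

The generator draws haplotypes from the classical three-point-cross class
frequencies with interference. Given interval recombination fractions r1, r2
and coefficient of coincidence c (observed / expected double crossovers;
c = 1 no interference, c < 1 positive, c > 1 negative interference):

    P4 = c·r1·r2              (double crossover)
    P3 = r1 − c·r1·r2         (single crossover, interval 1)
    P2 = r2 − c·r1·r2         (single crossover, interval 2)
    P1 = 1 − r1 − r2 + c·r1·r2  (parental)

so the RD statistic is Dr = (c − 1)·r1·r2 exactly — the quantity the
calibration helpers recover. Each collapsed class is split between its two
sister haplotypes by ``sister_split`` (default 0.5), controls are drawn
multinomially from the resulting 8-haplotype frequencies, and cases from the
same frequencies reweighted by a per-haplotype relative-risk map. Sampling is
at the haplotype level, matching the analyses, which count haplotypes — not
diplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .hap_table_io import HaplotypeTable, HapRow
from .sister_recode import complement

__all__ = [
    "SimConfig",
    "SimulationError",
    "class_frequencies",
    "haplotype_frequencies",
    "sample_case_control",
    "resample_table",
    "dr_recovery",
    "rd_type_i_error",
    "assoc_type_i_error",
]

_UNPRIMED = ("ABC", "ABc", "Abc", "AbC")  # class order P1..P4


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Three-locus crossover model with a per-haplotype disease-risk map.

    ``parental``/``alternate`` give the DNA bases mapped to the uppercase and
    lowercase letter at each of the three sites. ``risk`` maps DNA haplotypes
    to relative risks (absent haplotypes default to 1); ``sister_split`` is
    the fraction of each collapsed class assigned to the unprimed sister
    (scalar, or one value per class).
    """

    r1: float = 0.1
    r2: float = 0.2
    c: float = 1.0
    sister_split: float | Sequence[float] = 0.5
    risk: Mapping[str, float] = field(default_factory=dict)
    n_case: int = 500
    n_control: int = 500
    parental: str = "ACG"
    alternate: str = "CTA"
    site_ids: tuple[str, str, str] = ("S1", "S2", "S3")
    seed: int | None = None


def class_frequencies(r1: float, r2: float, c: float) -> np.ndarray:
    """Crossover-class frequencies (P1, P2, P3, P4) for given r1, r2, c."""
    if not (0 < r1 <= 0.5 and 0 < r2 <= 0.5):
        raise SimulationError("recombination fractions must lie in (0, 0.5]")
    if c < 0:
        raise SimulationError("coefficient of coincidence must be non-negative")
    p4 = c * r1 * r2
    P = np.array([1 - r1 - r2 + p4, r2 - p4, r1 - p4, p4])
    if (P < 0).any():
        raise SimulationError(
            f"negative class frequency for r1={r1}, r2={r2}, c={c}: "
            "c*r1*r2 must not exceed min(r1, r2)"
        )
    return P


def _geno_to_dna(geno: str, parental: str, alternate: str) -> str:
    return "".join(
        parental[i] if ch.isupper() else alternate[i] for i, ch in enumerate(geno)
    )


def haplotype_frequencies(config: SimConfig) -> dict[str, float]:
    """Population frequencies of the 8 DNA haplotypes (control distribution)."""
    P = class_frequencies(config.r1, config.r2, config.c)
    split = np.broadcast_to(np.asarray(config.sister_split, dtype=float), (4,))
    if ((split <= 0) | (split >= 1)).any():
        raise SimulationError("sister_split must lie in (0, 1)")
    freqs: dict[str, float] = {}
    for i, geno in enumerate(_UNPRIMED):
        dna = _geno_to_dna(geno, config.parental, config.alternate)
        dna_p = _geno_to_dna(complement(geno), config.parental, config.alternate)
        freqs[dna] = P[i] * split[i]
        freqs[dna_p] = P[i] * (1 - split[i])
    return freqs


def _case_frequencies(config: SimConfig, freqs: dict[str, float]) -> np.ndarray:
    w = np.array([freqs[h] * config.risk.get(h, 1.0) for h in freqs])
    total = w.sum()
    if total <= 0:
        raise SimulationError("degenerate case frequency vector (all risks zero?)")
    return w / total


def sample_case_control(
    config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypeTable:
    """Draw one multinomial case/control haplotype table under the model.

    Controls follow the crossover-class frequencies; cases follow the same
    frequencies reweighted by relative risk and renormalized. All 8
    haplotypes appear as rows (possibly with zero counts). Reproducible for
    a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = haplotype_frequencies(config)
    haps = list(freqs)
    p_control = np.array([freqs[h] for h in haps])
    p_case = _case_frequencies(config, freqs)
    case = rng.multinomial(config.n_case, p_case)
    ctrl = rng.multinomial(config.n_control, p_control)
    return HaplotypeTable(
        site_ids=list(config.site_ids),
        rows=[HapRow(h, float(a), float(b)) for h, a, b in zip(haps, case, ctrl)],
        n_case=float(config.n_case),
        n_control=float(config.n_control),
    )


def resample_table(
    table: HaplotypeTable, n_case: int, n_control: int, seed: int | None = None
) -> HaplotypeTable:
    """Multinomial resample of each arm at new sample sizes.

    Mirrors reassigning a chosen number of patients and healthy individuals
    to the observed haplotypes using their per-arm frequencies.
    """
    if n_case <= 0 or n_control <= 0:
        raise SimulationError("resample sizes must be positive")
    case_tot, ctrl_tot = table.total_case, table.total_control
    if case_tot <= 0 or ctrl_tot <= 0:
        raise SimulationError("cannot resample an arm with zero total count")
    rng = np.random.default_rng(seed)
    p_case = np.array([r.case_count for r in table.rows]) / case_tot
    p_ctrl = np.array([r.control_count for r in table.rows]) / ctrl_tot
    case = rng.multinomial(n_case, p_case)
    ctrl = rng.multinomial(n_control, p_ctrl)
    return HaplotypeTable(
        site_ids=list(table.site_ids),
        rows=[
            HapRow(r.haplotype, float(a), float(b))
            for r, a, b in zip(table.rows, case, ctrl)
        ],
        n_case=float(n_case),
        n_control=float(n_control),
    )


# ---------------------------------------------------------------------------
# Vectorized calibration helpers. These sample class counts directly (the
# collapse over sisters is a deterministic sum, so sampling the 4 collapsed
# classes is distributionally identical to sampling 8 haplotypes and
# collapsing) and apply the same closed forms the analysis modules use.
# ---------------------------------------------------------------------------


def _class_stats(counts: np.ndarray):
    """Vectorized (Dr, R1, R2, chisq, p) from (reps, 4) class counts."""
    n = counts.sum(axis=1)
    P = counts / n[:, None]
    R1 = P[:, 2] + P[:, 3]
    R2 = P[:, 1] + P[:, 3]
    Dr = P[:, 0] * P[:, 3] - P[:, 1] * P[:, 2]
    denom = R1 * (1 - R1) * R2 * (1 - R2)
    ok = denom > 0
    chisq = np.full(len(n), np.nan)
    chisq[ok] = n[ok] * Dr[ok] ** 2 / denom[ok]
    p = np.where(np.isnan(chisq), np.nan, stats.chi2.sf(chisq, df=1))
    return Dr, R1, R2, chisq, p


def dr_recovery(
    config: SimConfig, reps: int = 2000, seed: int | None = None
) -> dict[str, float]:
    """Monte-Carlo recovery of E[Dr] = (c−1)·r1·r2 from simulated tables.

    Returns the replicate mean and its standard error alongside the
    closed-form expectation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = class_frequencies(config.r1, config.r2, config.c)
    counts = rng.multinomial(config.n_control, P, size=reps).astype(float)
    Dr, *_ = _class_stats(counts)
    return {
        "mean_dr": float(Dr.mean()),
        "se_dr": float(Dr.std(ddof=1) / np.sqrt(reps)),
        "expected_dr": float((config.c - 1) * config.r1 * config.r2),
        "reps": reps,
    }


def rd_type_i_error(
    config: SimConfig,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Empirical rejection rate of the RD chi-square under the c = 1 null."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = class_frequencies(config.r1, config.r2, 1.0)
    counts = rng.multinomial(config.n_control, P, size=reps).astype(float)
    *_, p = _class_stats(counts)
    return float(np.nanmean(p < alpha))


def _chisq_2x2_arrays(a, b, c, d, yates: bool):
    n = a + b + c + d
    cross = np.abs(a * d - b * c)
    if yates:
        cross = np.maximum(0.0, cross - n / 2.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chisq = np.where(denom > 0, n * cross**2 / denom, np.nan)
    return np.where(np.isnan(chisq), np.nan, stats.chi2.sf(chisq, df=1))


def assoc_type_i_error(
    config: SimConfig,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """Per-sister-pair rejection rates under the all-risks-equal null.

    Case and control arms are drawn from the same haplotype distribution;
    rates are reported for both the plain and the Yates-corrected 2×2
    chi-square (the Yates form is conservative by construction). Replicates
    with a zero margin are excluded from the rate for that pair.
    """
    if config.risk:
        raise SimulationError("type-I calibration requires an all-risks-1 config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = haplotype_frequencies(config)
    haps = list(freqs)
    p = np.array([freqs[h] for h in haps])
    case = rng.multinomial(config.n_case, p, size=reps).astype(float)
    ctrl = rng.multinomial(config.n_control, p, size=reps).astype(float)
    idx = {h: i for i, h in enumerate(haps)}
    out: dict[str, dict[str, float]] = {}
    for geno in _UNPRIMED:
        h1 = _geno_to_dna(geno, config.parental, config.alternate)
        h2 = _geno_to_dna(complement(geno), config.parental, config.alternate)
        a, b = case[:, idx[h1]], case[:, idx[h2]]
        c_, d = ctrl[:, idx[h1]], ctrl[:, idx[h2]]
        p_plain = _chisq_2x2_arrays(a, b, c_, d, yates=False)
        p_yates = _chisq_2x2_arrays(a, b, c_, d, yates=True)
        out[f"{geno}/{complement(geno)}"] = {
            "plain": float(np.nanmean(p_plain < alpha)),
            "yates": float(np.nanmean(p_yates < alpha)),
        }
    return out
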