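"""Seeded generators for every input the analysis stages consume.

Each generator takes an explicit integer seed, draws from its own
``numpy.random.Generator`` (no hidden global state), and returns the
simulated data together with a machine-readable truth record so recovery
can be scored without re-deriving parameters.  Identical arguments and
seed give bit-identical output.

Defaults mirror the study conditions the generators emulate: ATP designs
spanning 10-5000 uM with 5% proportional velocity noise; 20-minute
regenerating-assay chromatograms with two Gaussian peaks whose areas split
according to the conversion fraction; genotype panels whose per-replicate
InsP6 amounts are drawn from the reported genotype means and SDs
(itpk4-1 26 +/- 1, Col0 153 +/- 39, ITPK4-OE 181 +/- 43 pmol per g fresh
weight, n = 3); and random protein backgrounds with embedded motif
substrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chromatography import CalibrationCurve, Chromatogram, RetentionWindow
from .kinetics import KineticParams, velocity

__all__ = [
    "GeneratorConfig",
    "DEFAULT_ATP_GRID",
    "GENOTYPE_INSP6_PMOL_PER_G",
    "INSP6_WINDOW",
    "gen_kinetic_dataset",
    "gen_assay_chromatogram",
    "gen_genotype_panel",
    "gen_motif_sequences",
]

#: ATP design grid (uM) spanning below and above both KM and the optimum.
DEFAULT_ATP_GRID = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2500.0, 5000.0)

#: Vegetative-tissue InsP6 content per genotype, mean/SD in pmol g-1 f.wt.
GENOTYPE_INSP6_PMOL_PER_G = {
    "itpk4-1": (26.0, 1.0),
    "Col0": (153.0, 39.0),
    "ITPK4-OE": (181.0, 43.0),
}

#: Retention window of the InsP6 peak in the synthetic gradient (minutes).
INSP6_WINDOW = RetentionWindow("InsP6", 24.0, 28.0, phosphate_count=6)

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario descriptor: seed + scenario id + parameter block."""

    seed: int
    scenario: str
    params: dict = field(default_factory=dict)


def gen_kinetic_dataset(
    params: KineticParams,
    design=DEFAULT_ATP_GRID,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy initial-rate table: v = model(S) * (1 + N(0, noise_cv)).

    Returns a DataFrame with columns S_uM, v and truth in ``attrs``.
    """
    design = np.asarray(design, dtype=float)
    if np.any(design < 0) or np.any(design > 5000):
        raise ValueError("ATP design must lie within 0-5000 uM")
    rng = np.random.default_rng(seed)
    v_true = np.asarray(velocity(params, design), dtype=float)
    v = v_true * (1.0 + noise_cv * rng.standard_normal(design.shape))
    df = pd.DataFrame({"S_uM": design, "v": v})
    df.attrs["truth"] = {
        "Vmax": params.Vmax,
        "KM": params.KM,
        "Ki": params.Ki,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return df


def _gaussian(t, apex, sigma, area):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - apex) / sigma) ** 2
    )


def _emg(t, apex, sigma, area, tau):
    """Exponentially modified Gaussian (tailing) with unit area scaling."""
    from scipy.stats import exponnorm

    k = tau / sigma
    return area * exponnorm.pdf(t, k, loc=apex, scale=sigma)


def gen_assay_chromatogram(
    conversion_fraction: float,
    total_area: float = 1000.0,
    substrate_apex_min: float = 8.0,
    product_apex_min: float = 14.0,
    sigma_min: float = 0.25,
    noise: float = 0.01,
    drift: float = 0.5,
    tailing_tau_min: float = 0.0,
    duration_min: float = 20.0,
    dt_min: float = 0.01,
    seed: int = 0,
) -> Chromatogram:
    """Two-peak regenerating-assay trace with a stated conversion fraction.

    Substrate and product peaks carry areas (1-f) and f times
    ``total_area``; ``noise`` is Gaussian with SD = noise * peak height
    scale, ``drift`` a linear baseline over the run.  Truth (areas, the
    fraction, seed) rides in ``metadata`` via the returned object's
    ``truth`` attribute.
    """
    if not 0 <= conversion_fraction <= 1:
        raise ValueError("conversion fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    sub_area = (1.0 - conversion_fraction) * total_area
    prod_area = conversion_fraction * total_area
    shape = _emg if tailing_tau_min > 0 else _gaussian
    extra = (tailing_tau_min,) if tailing_tau_min > 0 else ()
    y = shape(t, substrate_apex_min, sigma_min, sub_area, *extra)
    y = y + shape(t, product_apex_min, sigma_min, prod_area, *extra)
    height_scale = total_area / (sigma_min * np.sqrt(2 * np.pi))
    y = y + drift * t / duration_min
    y = y + noise * height_scale * rng.standard_normal(t.shape)
    chrom = Chromatogram(t, y, genotype="assay")
    chrom.truth = {
        "conversion_fraction": conversion_fraction,
        "substrate_area": sub_area,
        "product_area": prod_area,
        "substrate_apex_min": substrate_apex_min,
        "product_apex_min": product_apex_min,
        "sigma_min": sigma_min,
        "seed": seed,
    }
    return chrom


def gen_genotype_panel(
    genotype_stats: dict = None,
    n: int = 3,
    calibration: Optional[CalibrationCurve] = None,
    mass_g: float = 0.16,
    injected_fraction: float = 0.2,
    apex_min: float = 26.0,
    sigma_min: float = 0.2,
    noise_counts: float = 2.0,
    drift_counts: float = 5.0,
    duration_min: float = 35.0,
    dt_min: float = 0.02,
    seed: int = 0,
):
    """Multi-genotype LC-ICP-MS panel with an embedded InsP6 peak per trace.

    Per-replicate InsP6 amounts (pmol per g fresh weight) are drawn from
    Normal(mean, SD) per genotype, converted through the calibration to a
    peak area (area = pmol_injected * response_factor with pmol_injected =
    amount * mass * injected_fraction) and embedded as a Gaussian peak on
    a drifting, noisy baseline.

    Returns ``(traces, truth)`` where traces maps genotype -> list of
    Chromatogram and truth is a tidy DataFrame of the generating amounts.
    """
    if genotype_stats is None:
        genotype_stats = GENOTYPE_INSP6_PMOL_PER_G
    if n < 1:
        raise ValueError("need at least one replicate")
    if calibration is None:
        calibration = CalibrationCurve(response_factor=50.0)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    traces = {}
    truth_rows = []
    for genotype, (mean, sd) in genotype_stats.items():
        reps = []
        for rep in range(n):
            amount = max(0.0, float(rng.normal(mean, sd)))
            pmol_injected = amount * mass_g * injected_fraction
            area = pmol_injected * calibration.response_factor
            y = _gaussian(t, apex_min, sigma_min, area)
            y = y + drift_counts * t / duration_min
            y = y + noise_counts * rng.standard_normal(t.shape)
            reps.append(
                Chromatogram(
                    t,
                    y,
                    genotype=genotype,
                    mass_g=mass_g,
                    injected_fraction=injected_fraction,
                )
            )
            truth_rows.append(
                {
                    "genotype": genotype,
                    "replicate": rep,
                    "pmol_per_g": amount,
                    "area": area,
                }
            )
        traces[genotype] = reps
    truth = pd.DataFrame(truth_rows)
    truth.attrs["calibration"] = calibration
    truth.attrs["seed"] = seed
    return traces, truth


def gen_motif_sequences(
    n: int = 5,
    length: int = 120,
    embed=("DES",),
    embed_at: Optional[int] = None,
    seed: int = 0,
):
    """Random protein backgrounds with motif substrings embedded.

    Returns ``(records, truth)``: Biopython SeqRecords and a list of
    per-record dicts giving each embedded string and its 1-based start.
    """
    for s in embed:
        if not set(s) <= set(AA):
            raise ValueError(f"embed string {s!r} not over the amino-acid alphabet")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for i in range(n):
        seq = list(rng.choice(list(AA), size=length))
        placements = []
        occupied = []
        cursor = embed_at
        for s in embed:
            if cursor is not None:
                start = cursor
                cursor += len(s) + 5
            else:
                # rejection-sample a start that does not overlap earlier embeds
                for _ in range(200):
                    start = int(rng.integers(1, length - len(s) + 1))
                    if all(
                        start + len(s) <= a or start >= b for a, b in occupied
                    ):
                        break
                else:
                    raise ValueError("could not place embeds without overlap")
            if start < 1 or start + len(s) - 1 > length:
                raise ValueError("embed does not fit in the sequence")
            occupied.append((start, start + len(s)))
            seq[start - 1 : start - 1 + len(s)] = list(s)
            placements.append({"motif": s, "start": start})
        rec = SeqRecord(Seq("".join(seq)), id=f"synth_{i}", description="synthetic")
        records.append(rec)
        truth.append({"id": rec.id, "embedded": placements, "seed": seed})
    return records, truth
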