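"""Quantification of NAD(P)H-depletion plate-reader screens.

A carbonyl-reductase screen follows the oxidation of NAD(P)H as a drop in
absorbance at 340 nm.  Beer-Lambert converts the endpoint drop into cofactor
consumed (epsilon = 6220 per M per cm for both NADH and NADPH), and with
1:1 stoichiometry and no cofactor recycling that equals substrate reduced.

Two referenced percentages are always reported side by side: conversion
relative to the substrate loading and relative to the cofactor loading.
With the screen's typical 5 mM substrate and 1 mM cofactor the
substrate-referenced conversion is capped at 20% - the stoichiometric
ceiling - while the cofactor-referenced figure saturates at 100%; which of
the two a given report calls "conversion" varies between labs, so neither
is guessed here.

The optical path length of a plate well depends on fill volume and is a
required input; no default is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

EPSILON_NADPH = 6220.0  # per M per cm at 340 nm; same value used for NADH


@dataclass(frozen=True)
class AssayTrace:
    """One well's absorbance time course plus its assay metadata."""

    well_id: str
    enzyme_id: str
    substrate_id: str
    cofactor: str  # 'NADH' or 'NADPH'
    times: tuple[float, ...]  # seconds
    a340: tuple[float, ...]
    path_cm: float
    substrate_mM: float
    cofactor_mM: float

    def __post_init__(self) -> None:
        if self.cofactor not in ("NADH", "NADPH"):
            raise ValueError("cofactor must be 'NADH' or 'NADPH'")
        if len(self.times) != len(self.a340):
            raise ValueError("times and a340 must have equal length")
        if len(self.times) >= 2 and not all(
            b > a for a, b in zip(self.times, self.times[1:])
        ):
            raise ValueError("times must be strictly increasing")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be positive")
        if self.substrate_mM <= 0 or self.cofactor_mM <= 0:
            raise ValueError("concentrations must be positive")


def delta_to_nadph(
    trace: AssayTrace,
    epsilon: float = EPSILON_NADPH,
    blank: AssayTrace | None = None,
    endpoint: str = "final",
) -> float:
    """Cofactor consumed (mM) from the endpoint absorbance drop.

    ``endpoint='final'`` uses the last cycle (the screen reads after the
    full incubation); ``'min'`` uses the minimum absorbance, for noisy
    traces.  A blank trace's drop is subtracted when given.  The result is
    clipped to [0, cofactor_mM]; exceeding the cofactor loading triggers a
    warning since it implies recycling or an artefact.
    """
    if len(trace.times) < 2:
        raise ValueError("need at least 2 time points")
    if endpoint not in ("final", "min"):
        raise ValueError("endpoint must be 'final' or 'min'")

    def drop(t: AssayTrace) -> float:
        a = np.asarray(t.a340)
        end = a[-1] if endpoint == "final" else a.min()
        return float(a[0] - end)

    delta = drop(trace)
    if blank is not None:
        delta -= drop(blank)
    consumed_mM = 1000.0 * delta / (epsilon * trace.path_cm)
    if consumed_mM > trace.cofactor_mM:
        warnings.warn(
            f"well {trace.well_id}: absorbance drop exceeds the Beer-Lambert "
            f"equivalent of the cofactor loading; clipping to {trace.cofactor_mM} mM",
            stacklevel=2,
        )
    return float(np.clip(consumed_mM, 0.0, trace.cofactor_mM))


def conversion_percent(
    consumed_mM: float,
    substrate_mM: float,
    cofactor_mM: float | None = None,
) -> tuple[float, float | None]:
    """(substrate-referenced, cofactor-referenced) conversion percentages.

    1:1 stoichiometry: one cofactor oxidised per carbonyl reduced.  The
    cofactor-referenced figure is None when no cofactor loading is given.
    """
    if substrate_mM <= 0:
        raise ValueError("substrate_mM must be positive")
    sub_pct = 100.0 * consumed_mM / substrate_mM
    cof_pct = 100.0 * consumed_mM / cofactor_mM if cofactor_mM else None
    return sub_pct, cof_pct


def initial_rate(
    trace: AssayTrace,
    n_points: int = 10,
    epsilon: float = EPSILON_NADPH,
    volume_uL: float = 200.0,
) -> tuple[float, float]:
    """Initial slope of a trace: (delta-A per minute, umol per minute).

    Least-squares fit over the first ``n_points`` cycles; the molar rate
    uses Beer-Lambert and the well volume.  The slope is negative for a
    depleting (active) well.
    """
    if n_points < 2 or n_points > len(trace.times):
        raise ValueError("n_points must be in [2, len(trace)]")
    t_min = np.asarray(trace.times[:n_points]) / 60.0
    a = np.asarray(trace.a340[:n_points])
    slope = float(np.polyfit(t_min, a, 1)[0])  # delta-A / min
    rate_M_per_min = slope / (epsilon * trace.path_cm)
    umol_per_min = rate_M_per_min * (volume_uL * 1e-6) * 1e6
    return slope, umol_per_min


def screen_matrix(
    traces: Iterable[AssayTrace],
    hit_threshold: float = 10.0,
    epsilon: float = EPSILON_NADPH,
    blanks: dict[str, AssayTrace] | None = None,
    endpoint: str = "final",
) -> pd.DataFrame:
    """Aggregate traces into an enzyme x substrate x cofactor screen table.

    Replicate wells (same enzyme, substrate and cofactor) are averaged with
    a standard deviation column; a combination is a hit when its mean
    substrate-referenced conversion reaches ``hit_threshold`` percent.
    Replicates with conflicting concentrations or path lengths are an
    error.  ``blanks`` maps well_id to a reference trace.
    """
    rows = []
    for tr in traces:
        blank = blanks.get(tr.well_id) if blanks else None
        consumed = delta_to_nadph(tr, epsilon=epsilon, blank=blank, endpoint=endpoint)
        sub_pct, cof_pct = conversion_percent(consumed, tr.substrate_mM, tr.cofactor_mM)
        rows.append(
            {
                "enzyme_id": tr.enzyme_id,
                "substrate_id": tr.substrate_id,
                "cofactor": tr.cofactor,
                "well_id": tr.well_id,
                "substrate_mM": tr.substrate_mM,
                "cofactor_mM": tr.cofactor_mM,
                "path_cm": tr.path_cm,
                "consumed_mM": consumed,
                "conversion_substrate_pct": sub_pct,
                "conversion_cofactor_pct": cof_pct,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "enzyme_id", "substrate_id", "cofactor", "n_wells",
                "consumed_mM_mean", "conversion_substrate_pct_mean",
                "conversion_substrate_pct_sd", "conversion_cofactor_pct_mean",
                "hit",
            ]
        )
    df = pd.DataFrame(rows)
    keys = ["enzyme_id", "substrate_id", "cofactor"]
    for _, grp in df.groupby(keys):
        for col in ("substrate_mM", "cofactor_mM", "path_cm"):
            if grp[col].nunique() > 1:
                raise ValueError(
                    f"conflicting {col} among replicate wells {sorted(grp['well_id'])}"
                )
    out = (
        df.groupby(keys)
        .agg(
            n_wells=("well_id", "size"),
            consumed_mM_mean=("consumed_mM", "mean"),
            conversion_substrate_pct_mean=("conversion_substrate_pct", "mean"),
            conversion_substrate_pct_sd=("conversion_substrate_pct", "std"),
            conversion_cofactor_pct_mean=("conversion_cofactor_pct", "mean"),
        )
        .reset_index()
    )
    out["hit"] = out["conversion_substrate_pct_mean"] >= hit_threshold
    return out


def simulate_trace(
    well_id: str,
    enzyme_id: str,
    substrate_id: str,
    active: bool,
    seed: int = 0,
    cofactor: str = "NADPH",
    n_cycles: int = 100,
    cycle_s: float = 57.0,
    a0: float = 3.2,  # ~1 mM NAD(P)H over 0.5 cm plus background
    rate_per_min: float = 0.05,
    noise_sd: float = 0.002,
    path_cm: float = 0.5,
    substrate_mM: float = 5.0,
    cofactor_mM: float = 1.0,
) -> AssayTrace:
    """Synthetic plate-reader trace for benchmarks and tests.

    Active wells decay exponentially toward the absorbance floor left when
    the cofactor is exhausted; inactive wells stay flat.  Gaussian noise of
    ``noise_sd`` absorbance units is added either way.  The defaults mirror
    the screening conditions (100 cycles of 57 s, 5 mM substrate, 1 mM
    cofactor).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_cycles) * cycle_s
    floor = a0 - EPSILON_NADPH * path_cm * cofactor_mM / 1000.0
    if active:
        a = floor + (a0 - floor) * np.exp(-rate_per_min * t / 60.0)
    else:
        a = np.full(n_cycles, a0)
    a = a + rng.normal(0.0, noise_sd, size=n_cycles)
    return AssayTrace(
        well_id=well_id,
        enzyme_id=enzyme_id,
        substrate_id=substrate_id,
        cofactor=cofactor,
        times=tuple(t.tolist()),
        a340=tuple(a.tolist()),
        path_cm=path_cm,
        substrate_mM=substrate_mM,
        cofactor_mM=cofactor_mM,
    )


def read_trace_tsv(path) -> list[AssayTrace]:
    """Read long-format trace TSV: one row per (well, cycle) reading.

    Columns: well, enzyme, substrate, cofactor, time_s, a340, path_cm,
    substrate_mM, cofactor_mM.
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "well", "enzyme", "substrate", "cofactor", "time_s", "a340",
        "path_cm", "substrate_mM", "cofactor_mM",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace TSV missing columns: {sorted(missing)}")
    traces = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_s")
        meta = grp.iloc[0]
        traces.append(
            AssayTrace(
                well_id=str(well),
                enzyme_id=str(meta["enzyme"]),
                substrate_id=str(meta["substrate"]),
                cofactor=str(meta["cofactor"]),
                times=tuple(grp["time_s"].tolist()),
                a340=tuple(grp["a340"].tolist()),
                path_cm=float(meta["path_cm"]),
                substrate_mM=float(meta["substrate_mM"]),
                cofactor_mM=float(meta["cofactor_mM"]),
            )
        )
    return traces


def write_screen_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
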