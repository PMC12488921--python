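"""End-to-end orchestration: simulate, analyze and write all artifacts.

`run_pipeline` binds the stages together in dependency order
(population → events → histogram → sedimentation → fusion → kinetics →
refractometry → solution chemistry), writes the CSV/JSON artifacts, and
records a run log with per-stage seeds and a parameter hash so that an
identical configuration and seed reproduce byte-identical numeric
outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .errors import ConfigurationError
from .hydrodynamics import CTX_20W, correct_distribution_s20w, fuse_distributions
from .kinetics import arrhenius_from_series, rate_and_timescale
from .mass_photometry import (
    build_histogram,
    mean_aggregation_number,
    to_mass_weighted,
)
from .solution_chemistry import debye_length, ionic_strength, phosphate_speciation
from .synthetic import (
    KineticParams,
    PopulationParams,
    build_population,
    derive_seed,
    forward_auc,
    sample_mp_events,
    simulate_dissociation,
    simulate_refractometry,
)

ALL_STAGES = ("population", "mp", "auc", "fusion", "kinetics", "refractometry", "chem")

STAGE_DEPENDENCIES = {
    "mp": ("population",),
    "auc": ("population",),
    "fusion": ("mp", "auc"),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    All stochastic stages derive their substream from the single global
    seed and the stage name, so disabling one stage never shifts the
    randomness of another.
    """

    seed: int = 0
    stages: tuple = ALL_STAGES
    out_dir: str = "micellab_run"
    total_conc_um: float = 30.0
    pH_label: str = "pH8"
    n_events: int = 10_000
    temperatures_c: tuple = (22.0, 25.0, 28.0, 31.0, 34.0, 37.0, 40.0)
    replicates: int = 3
    population: PopulationParams = field(default_factory=PopulationParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    buffer_phosphate_mm: float = 20.0
    buffer_ph: float = 8.0

    def parameter_hash(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k != "out_dir"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the artifact bundle.

    Returns a dict of in-memory results; all tabular artifacts are also
    written under ``config.out_dir`` together with ``run_log.json``.
    """
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    for stage, deps in STAGE_DEPENDENCIES.items():
        if stage in config.stages:
            missing = [d for d in deps if d not in config.stages]
            if missing:
                raise ConfigurationError(
                    f"stage {stage!r} requires {missing} to be enabled"
                )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "parameter_hash": config.parameter_hash(),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
    }
    bundle: dict = {}

    def record(stage: str, **extra) -> None:
        log["stages"].append({"stage": stage, "time": time.time(), **extra})

    if "population" in config.stages:
        pop = build_population(config.population, config.total_conc_um, config.pH_label)
        bundle["population"] = pop
        record("population", pH=config.pH_label, total_conc_um=config.total_conc_um)

    if "mp" in config.stages:
        sub = derive_seed(config.seed, "mp")
        events = sample_mp_events(bundle["population"], config.n_events, seed=sub)
        hist = build_histogram(events.measured_mass, config.population.monomer_mass)
        hist_mw = to_mass_weighted(hist)
        stats = mean_aggregation_number(hist_mw, n_min=3)
        bundle.update(events=events, histogram=hist, histogram_mass_weighted=hist_mw,
                      mean_aggregation=stats)
        mio.write_events(events, out / "events.csv")
        mio.write_histogram(hist_mw, out / "histogram_mass_weighted.csv")
        record("mp", seed=sub, mean_n=stats.value, weighting=stats.weighting)

    if "auc" in config.stages:
        sed = forward_auc(bundle["population"], temperature_c=20.0)
        sed = correct_distribution_s20w(sed)
        bundle["sedimentation"] = sed
        mio.write_sedimentation(sed, out / "sedimentation.csv")
        record("auc", n_points=len(sed.s_values))

    if "fusion" in config.stages:
        fused = fuse_distributions(
            bundle["histogram_mass_weighted"], bundle["sedimentation"], CTX_20W
        )
        bundle["fused"] = fused
        mio.write_fused(fused, out / "fused.csv")
        record("fusion", mean_rh_nm=fused.weighted_mean_rh())

    if "kinetics" in config.stages:
        sub = derive_seed(config.seed, "kinetics")
        series = simulate_dissociation(
            config.kinetics,
            [t + 273.15 for t in config.temperatures_c],
            replicates=config.replicates,
            seed=sub,
        )
        arr = arrhenius_from_series(series)
        k37, tau37 = rate_and_timescale(arr, 310.15)
        bundle.update(series=series, arrhenius=arr)
        mio.write_series(series, out / "dissociation_series.csv")
        (out / "arrhenius.json").write_text(
            json.dumps(
                {
                    "Ea_kJ_mol": arr.Ea,
                    "lnA": arr.lnA,
                    "se_Ea_kJ_mol": arr.se_Ea,
                    "k_37C_per_s": k37,
                    "timescale_37C_min": tau37 / 60.0,
                    "points": [(t, k, src) for t, k, src in arr.points],
                },
                indent=2,
            )
        )
        record("kinetics", seed=sub, Ea_kJ_mol=arr.Ea)

    if "refractometry" in config.stages:
        sub = derive_seed(config.seed, "refractometry")
        refract = simulate_refractometry(seed=sub)
        bundle["refractometry"] = refract
        mio.write_refractometry(refract, out / "refractometry.csv")
        record("refractometry", seed=sub)

    if "chem" in config.stages:
        species = phosphate_speciation(config.buffer_phosphate_mm, config.buffer_ph)
        i_mm = ionic_strength(species)
        debye_nm = debye_length(i_mm)
        bundle["buffer"] = {"species": species, "ionic_strength_mM": i_mm,
                            "debye_length_nm": debye_nm}
        (out / "buffer.json").write_text(
            json.dumps(
                {
                    "species": [asdict(s) for s in species],
                    "ionic_strength_mM": i_mm,
                    "debye_length_nm": debye_nm,
                },
                indent=2,
            )
        )
        record("chem", ionic_strength_mM=i_mm)

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    bundle["log"] = log
    return bundle
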