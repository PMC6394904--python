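"""Campaign drivers: domain-size sweeps, one-at-a-time kinetics sweeps, stimulus studies.

Each campaign runs ``reps`` independent replicates per condition, with one
pseudo-random stream per replicate seeded from (base seed, condition
index, replicate index), and returns a :class:`CampaignResult` holding a
long-form table (one row per replicate) plus a manifest sufficient to
reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .model import GMParameters, scale_parameter
from .domains import ring_from_front_area, sphere_from_front_area
from .simulate import SimConfig, run_one
from .stimuli import StimulusSpec, pattern_centers

__all__ = [
    "CampaignResult",
    "domain_size_sweep",
    "oat_kinetics_sweep",
    "stimulus_campaign",
    "summarize",
    "DEFAULT_AREAS",
    "DEFAULT_FACTORS",
]

#: Front-view areas of the size sweep: 250..1450 um^2 in steps of 50.
DEFAULT_AREAS = tuple(np.arange(250.0, 1451.0, 50.0))

#: Kinetics sweep factors: 20%..300% in steps of 20%.
DEFAULT_FACTORS = tuple(np.round(np.arange(0.2, 3.01, 0.2), 10))

#: A spike counts as "at the stimulus" within this chord distance (um);
#: two e-foldings of the unit-width stimulus bump.
STIMULUS_MATCH_DIST = 2.0


@dataclass
class CampaignResult:
    table: pd.DataFrame
    manifest: dict

    def save(self, csv_path: str, manifest_path: str | None = None) -> None:
        self.table.to_csv(csv_path, index=False)
        if manifest_path:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest, fh, indent=2, default=str)


def _make_domain(domain_type: str, area: float, n_nodes: int, resolution: int):
    if domain_type == "ring":
        return ring_from_front_area(area, n_nodes)
    if domain_type == "sphere":
        return sphere_from_front_area(area, resolution)
    raise ValueError(f"unknown domain type {domain_type!r}")


def _replicate_row(params, domain, base_seed, cond_index, rep, sim_kwargs, stimulus=None):
    config = SimConfig(seed=[int(base_seed), int(cond_index), int(rep)], **sim_kwargs)
    result, label = run_one(params, domain, config, stimulus_spec=stimulus)
    row = {
        "replicate": rep,
        "seed": f"{base_seed}/{cond_index}/{rep}",
        "n_spikes": label.n_spikes,
        "geometry": label.geometry,
        "label": f"{label.n_spikes}:{label.geometry}",
        "converged": result.converged,
        "elapsed_model_time": result.elapsed_model_time,
    }
    if stimulus is not None and label.geometry not in ("failed", "none"):
        centers = pattern_centers(domain, stimulus.pattern)
        hit = False
        if len(centers) and label.spike_centers:
            spikes = np.asarray(label.spike_centers) * domain.radius
            d = np.linalg.norm(spikes[:, None, :] - centers[None, :, :], axis=2)
            hit = bool(d.min() <= STIMULUS_MATCH_DIST)
        row["spike_at_stimulus"] = hit
    return row


def domain_size_sweep(
    domain_type: str,
    areas=DEFAULT_AREAS,
    reps: int = 25,
    base_seed: int = 0,
    params: GMParameters | None = None,
    n_nodes: int = 256,
    resolution: int = 3,
    sim_kwargs: dict | None = None,
) -> CampaignResult:
    """Vary front-view area at fixed wild-type kinetics and tabulate labels."""
    params = params or GMParameters()
    sim_kwargs = sim_kwargs or {}
    rows = []
    for ci, area in enumerate(areas):
        domain = _make_domain(domain_type, area, n_nodes, resolution)
        for rep in range(reps):
            row = _replicate_row(params, domain, base_seed, ci, rep, sim_kwargs)
            row.update(domain_type=domain_type, front_area=area, parameter_name="", scale_factor=1.0)
            rows.append(row)
    manifest = {
        "campaign": "domain_size_sweep",
        "domain_type": domain_type,
        "areas": list(map(float, areas)),
        "reps": reps,
        "base_seed": base_seed,
        "params": asdict(params),
        "n_nodes": n_nodes,
        "resolution": resolution,
        "sim_kwargs": sim_kwargs,
    }
    return CampaignResult(pd.DataFrame(rows), manifest)


def oat_kinetics_sweep(
    parameter_name: str,
    domain_type: str = "ring",
    area: float = 550.0,
    factors=DEFAULT_FACTORS,
    reps: int = 25,
    base_seed: int = 0,
    params: GMParameters | None = None,
    n_nodes: int = 256,
    resolution: int = 3,
    sim_kwargs: dict | None = None,
) -> CampaignResult:
    """One-parameter-at-a-time sweep of a kinetic constant over scale factors."""
    params = params or GMParameters()
    sim_kwargs = sim_kwargs or {}
    rows = []
    domain = _make_domain(domain_type, area, n_nodes, resolution)
    for ci, factor in enumerate(factors):
        scaled = scale_parameter(params, parameter_name, factor)
        for rep in range(reps):
            row = _replicate_row(scaled, domain, base_seed, ci, rep, sim_kwargs)
            row.update(
                domain_type=domain_type,
                front_area=area,
                parameter_name=parameter_name,
                scale_factor=factor,
            )
            rows.append(row)
    manifest = {
        "campaign": "oat_kinetics_sweep",
        "parameter_name": parameter_name,
        "domain_type": domain_type,
        "front_area": area,
        "factors": list(map(float, factors)),
        "reps": reps,
        "base_seed": base_seed,
        "params": asdict(params),
        "n_nodes": n_nodes,
        "resolution": resolution,
        "sim_kwargs": sim_kwargs,
    }
    return CampaignResult(pd.DataFrame(rows), manifest)


def stimulus_campaign(
    mode: str,
    pattern: str,
    amplitudes,
    domain_areas=(550.0, 750.0),
    reps: int = 25,
    base_seed: int = 0,
    params: GMParameters | None = None,
    resolution: int = 3,
    sim_kwargs: dict | None = None,
) -> CampaignResult:
    """Transient or continuous stimulus study on sphere domains.

    Rows additionally record whether a resulting spike formed at a
    stimulus center (``spike_at_stimulus``); diverged runs are recorded as
    ``failed`` rows rather than aborting.
    """
    params = params or GMParameters()
    sim_kwargs = sim_kwargs or {}
    rows = []
    ci = 0
    for area in domain_areas:
        domain = sphere_from_front_area(area, resolution)
        for amp in amplitudes:
            spec = StimulusSpec(mode=mode, pattern=pattern, amplitude=float(amp))
            for rep in range(reps):
                row = _replicate_row(params, domain, base_seed, ci, rep, sim_kwargs, stimulus=spec)
                row.update(
                    domain_type="sphere",
                    front_area=area,
                    stimulus_mode=mode,
                    stimulus_pattern=pattern,
                    stimulus_amplitude=float(amp),
                )
                rows.append(row)
            ci += 1
    manifest = {
        "campaign": "stimulus_campaign",
        "mode": mode,
        "pattern": pattern,
        "amplitudes": list(map(float, amplitudes)),
        "domain_areas": list(map(float, domain_areas)),
        "reps": reps,
        "base_seed": base_seed,
        "params": asdict(params),
        "resolution": resolution,
        "sim_kwargs": sim_kwargs,
    }
    return CampaignResult(pd.DataFrame(rows), manifest)


def summarize(result: CampaignResult, by=None) -> pd.DataFrame:
    """Per-condition label frequency table (counts and fractions).

    Failed/diverged runs appear as their own ``0:failed`` label category.
    """
    df = result.table
    if df.empty:
        return pd.DataFrame(columns=["label", "count", "fraction"])
    if by is None:
        by = [
            c
            for c in (
                "domain_type",
                "front_area",
                "parameter_name",
                "scale_factor",
                "stimulus_mode",
                "stimulus_pattern",
                "stimulus_amplitude",
            )
            if c in df.columns
        ]
    out = df.groupby(by + ["label"], dropna=False).size().rename("count").reset_index()
    totals = out.groupby(by)["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out
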