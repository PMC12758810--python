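"""End-to-end experiment orchestration.

A single :class:`ExperimentConfig` drives: network generation (or
loading) -> dead-end pruning -> core/periphery labelling -> compression
(variant dependent) -> coupled flow/haematocrit solve -> source
projection -> steady oxygen and quasi-steady drug solves -> efficacy
metrics.  Everything is reproducible from (config, seed); outputs carry a
config hash and the package version.

The two model variants are ``core_compressed`` (core vessels squeezed to
aspect ratio 4.26) and ``core_uncompressed`` (no compression anywhere).
Sweeps reuse the factorised tissue operators: the steady matrices depend
only on source geometry, so an inlet-haematocrit sweep is one
factorisation and many right-hand sides, and a time sweep is a single
drug solve rescaled by C_plasma(t)/C_plasma(0).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .generate import NetworkGenConfig, generate_network
from .hemodynamics import BloodModelParams, FlowState, solve_coupled
from .metrics import (
    RegionMasks,
    Thresholds,
    bivariate_morans_I,
    build_region_masks,
    class_fractions,
    classify_efficacy,
    hypoxic_fraction,
    overlap_index,
    queen_weights,
)
from .network import (
    VascularNetwork,
    apply_compression,
    label_regions,
    prune_dead_ends,
    read_network,
    write_network,
)
from .pk import PKParams, load_default_pk, plasma_concentration
from .transport import (
    LinearTissueOperator,
    OxygenParams,
    ScalarField,
    SourceProjection,
    TissueGrid,
    drug_operator,
    load_default_oxygen,
    oxygen_operator,
    project_line_sources,
    solve_drug_quasisteady,
    solve_oxygen,
)

logger = logging.getLogger("microperf")

__all__ = ["ExperimentConfig", "RunResult", "run_model", "compare_variants",
           "sweep_inlet_haematocrit", "sweep_time"]

VARIANTS = ("core_compressed", "core_uncompressed")


@dataclass
class ExperimentConfig:
    variant: str = "core_compressed"
    network_path: Optional[str] = None       # load instead of generating
    seed: int = 0
    domain_size: float = 5000.0
    grid_h: float = 10.0
    core_radius: float = 1000.0
    aspect_ratio: float = 4.26
    inlet_haematocrit: float = 0.30
    evaluation_time_day: float = 1.0         # drug evaluated at C_plasma(t)
    hypoxia_mmHg: float = 8.0
    ic50_nM: float = 2.9
    output_dir: Optional[str] = None
    generator: Dict = field(default_factory=dict)   # NetworkGenConfig overrides

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (0 < self.inlet_haematocrit < 1):
            raise ValueError("inlet haematocrit must lie in (0, 1)")
        if self.evaluation_time_day < 0:
            raise ValueError("evaluation time must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def thresholds(self) -> Thresholds:
        return Thresholds(hypoxia_mmHg=self.hypoxia_mmHg, ic50_nM=self.ic50_nM)


@dataclass
class RunResult:
    config: ExperimentConfig
    network: VascularNetwork
    flow: FlowState
    grid: TissueGrid
    oxygen: ScalarField
    drug: ScalarField
    masks: RegionMasks
    metrics: Dict[str, float]


def _prepare_network(config: ExperimentConfig) -> VascularNetwork:
    if config.network_path:
        net = read_network(config.network_path)
    else:
        gen_kwargs = dict(domain_size=config.domain_size, seed=config.seed)
        gen_kwargs.update(config.generator)
        net = generate_network(NetworkGenConfig(**gen_kwargs))
    net = prune_dead_ends(net)
    labels = label_regions(net, config.core_radius)
    aspect = config.aspect_ratio if config.variant == "core_compressed" else 1.0
    return apply_compression(net, labels, aspect)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _metrics_block(
    oxygen: ScalarField,
    drug: ScalarField,
    masks: RegionMasks,
    thresholds: Thresholds,
    weights_core=None,
) -> Dict[str, float]:
    emap = classify_efficacy(oxygen, drug, thresholds)
    out: Dict[str, float] = {}
    for region, mask in (("core", masks.core), ("periphery", masks.periphery)):
        fr = class_fractions(emap, mask)
        for c in (1, 2, 3, 4):
            out[f"class{c}_{region}"] = fr[c]
        out[f"hypoxic_fraction_{region}"] = hypoxic_fraction(oxygen, mask, thresholds)
        out[f"mean_o2_{region}"] = float(oxygen.values[mask].mean())
        out[f"median_o2_{region}"] = float(np.median(oxygen.values[mask]))
        out[f"mean_drug_{region}"] = float(drug.values[mask].mean())
    _, omean, osd = overlap_index(drug, oxygen, masks.core)
    out["overlap_mean_core"] = omean
    out["overlap_sd_core"] = osd
    w = weights_core if weights_core is not None else queen_weights(masks.core)
    out["morans_I_core"] = bivariate_morans_I(
        oxygen, drug, masks.core, weights=w, symmetric=True)
    return out


def run_model(
    config: ExperimentConfig,
    pk: Optional[PKParams] = None,
    oxygen_params: Optional[OxygenParams] = None,
    blood: Optional[BloodModelParams] = None,
) -> RunResult:
    """Run one variant end to end and compute the efficacy metrics."""
    pk = pk or load_default_pk()
    oxygen_params = oxygen_params or load_default_oxygen()
    blood = blood or BloodModelParams(inlet_haematocrit=config.inlet_haematocrit)

    network = _stage("network")(_prepare_network)(config)
    flow = _stage("flow")(solve_coupled)(network, blood)
    grid = TissueGrid.from_network(network, config.grid_h)
    sources = _stage("project")(project_line_sources)(network, flow, grid)
    oxygen = _stage("oxygen")(solve_oxygen)(grid, sources, oxygen_params)
    cp = plasma_concentration(config.evaluation_time_day, pk)
    drug = _stage("drug")(solve_drug_quasisteady)(grid, sources, pk, cp)
    masks = build_region_masks(grid, network.centre, config.core_radius)
    metrics = _metrics_block(oxygen, drug, masks, config.thresholds())
    metrics["c_plasma_nM"] = cp
    result = RunResult(config=config, network=network, flow=flow, grid=grid,
                       oxygen=oxygen, drug=drug, masks=masks, metrics=metrics)
    if config.output_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: RunResult) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config.hash(), "version": __version__}
    write_network(result.network, out / "network.txt")
    result.oxygen.write_text(out / "oxygen_mmHg.txt")
    result.drug.write_text(out / "drug_nM.txt")
    per_vessel = pd.DataFrame({
        "vessel_id": [v.id for v in result.network.vessels],
        "diameter_um": [v.diameter for v in result.network.vessels],
        "compressed": [int(v.compressed) for v in result.network.vessels],
        "flow": result.flow.flow,
        "haematocrit": result.flow.haematocrit,
    })
    per_vessel.to_csv(out / "vessels.csv", index=False, float_format="%.10g")
    table = pd.DataFrame([{**stamp, **result.metrics}])
    table.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    with open(out / "provenance.json", "w") as fh:
        json.dump({**stamp, "config": dataclasses.asdict(result.config)},
                  fh, indent=2, sort_keys=True)


def compare_variants(
    config: ExperimentConfig,
    **kwargs,
) -> Dict[str, RunResult]:
    """Run both variants on the same network/seed and return both results."""
    out = {}
    for variant in VARIANTS:
        cfg = dataclasses.replace(config, variant=variant)
        if cfg.output_dir:
            cfg = dataclasses.replace(cfg, output_dir=str(Path(cfg.output_dir) / variant))
        out[variant] = run_model(cfg, **kwargs)
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

class _VariantSolvers:
    """Shared per-network solver state reused across sweep points."""

    def __init__(self, config, variant, pk, oxygen_params):
        cfg = dataclasses.replace(config, variant=variant, output_dir=None)
        self.config = cfg
        self.network = _prepare_network(cfg)
        self.grid = TissueGrid.from_network(self.network, cfg.grid_h)
        self.masks = build_region_masks(self.grid, self.network.centre, cfg.core_radius)
        self.weights = queen_weights(self.masks.core)
        self.pk = pk
        self.oxygen_params = oxygen_params
        self._oxy_op: Optional[LinearTissueOperator] = None
        self._drug_op: Optional[LinearTissueOperator] = None

    def solve_at(self, inlet_h: float) -> Tuple[ScalarField, ScalarField]:
        blood = BloodModelParams(inlet_haematocrit=inlet_h)
        flow = solve_coupled(self.network, blood)
        sources = project_line_sources(self.network, flow, self.grid)
        # geometry (and hence both matrices) is identical across sweep
        # points; only the right-hand sides change with haematocrit
        if self._oxy_op is None:
            self._oxy_op = oxygen_operator(self.grid, sources, self.oxygen_params)
            self._drug_op = drug_operator(self.grid, sources, self.pk)
        oxy = solve_oxygen(self.grid, sources, self.oxygen_params,
                           operator=self._oxy_op)
        cp = plasma_concentration(self.config.evaluation_time_day, self.pk)
        drug = solve_drug_quasisteady(self.grid, sources, self.pk, cp,
                                      operator=self._drug_op)
        return oxy, drug


def sweep_inlet_haematocrit(
    config: ExperimentConfig,
    values: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    pk: Optional[PKParams] = None,
    oxygen_params: Optional[OxygenParams] = None,
) -> pd.DataFrame:
    """Class fractions and Moran's I versus inlet discharge haematocrit.

    Both variants are evaluated at each sweep value on the same network.
    """
    values = list(values)
    if len(values) < 2:
        raise ValueError("sweep needs at least 2 inlet haematocrit values")
    if any(not (0 < v < 1) for v in values):
        raise ValueError("sweep values must lie in (0, 1)")
    pk = pk or load_default_pk()
    oxygen_params = oxygen_params or load_default_oxygen()
    rows = []
    for variant in VARIANTS:
        solver = _VariantSolvers(config, variant, pk, oxygen_params)
        for h_in in values:
            oxy, drug = solver.solve_at(h_in)
            m = _metrics_block(oxy, drug, solver.masks,
                               config.thresholds(), solver.weights)
            rows.append({"variant": variant, "inlet_haematocrit": h_in, **m})
    return pd.DataFrame(rows)


def sweep_time(
    config: ExperimentConfig,
    times_day: Sequence[float] = (0.0, 1.0, 3.0, 7.0, 14.0, 21.0),
    ic50_values: Sequence[float] = (2.9, 6.8),
    pk: Optional[PKParams] = None,
    oxygen_params: Optional[OxygenParams] = None,
) -> pd.DataFrame:
    """Efficacy versus time since bolus, at each IC50.

    The quasi-steady drug field is linear in C_plasma, so one solve per
    variant is rescaled by C_plasma(t)/C_plasma(0) for every time point.
    """
    times = sorted(times_day)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    pk = pk or load_default_pk()
    oxygen_params = oxygen_params or load_default_oxygen()
    rows = []
    for variant in VARIANTS:
        solver = _VariantSolvers(config, variant, pk, oxygen_params)
        oxy, drug0 = solver.solve_at(config.inlet_haematocrit)
        cp0 = plasma_concentration(config.evaluation_time_day, pk)
        for t in times:
            scale = plasma_concentration(t, pk) / cp0
            drug = ScalarField(grid=drug0.grid, values=drug0.values * scale,
                               units=drug0.units)
            for ic50 in ic50_values:
                thr = Thresholds(hypoxia_mmHg=config.hypoxia_mmHg, ic50_nM=ic50)
                m = _metrics_block(oxy, drug, solver.masks, thr, solver.weights)
                rows.append({"variant": variant, "time_day": t,
                             "ic50_nM": ic50, **m})
    return pd.DataFrame(rows)
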