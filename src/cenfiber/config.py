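"""Pipeline configuration: YAML in, validated parameter blocks out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError, ValidationError
from .footprints import CallingParams
from .occupancy import ClassifyParams
from .simulate import (
    CentromereModel,
    DistanceGenParams,
    MethylationParams,
    RuptureGenParams,
)

__all__ = ["SpeciesBlock", "PipelineConfig", "load_config", "default_demo_config"]

ALL_STAGES = ("simulate", "call", "occupancy", "rupture", "geometry")


@dataclass(frozen=True)
class SpeciesBlock:
    """One synthetic species: genome shape plus centromere architecture."""

    name: str
    n_chrom: int = 8
    chrom_length: int = 40_000
    at_fraction: float = 0.6
    cen_model: str = "single"
    protected_width: int | tuple[int, int, int] = 227
    cde_lengths: tuple[int, int, int] = (8, 165, 25)
    n_fibers: int = 400
    fiber_len_mean: float = 15_000.0
    fiber_len_sd: float = 3_000.0
    p_meth_accessible: float = 0.8
    p_meth_protected: float = 0.02

    def centromere_specs(self) -> list[CentromereModel]:
        total = sum(self.cde_lengths)
        specs = []
        for i in range(self.n_chrom):
            center = self.chrom_length // 2
            start = center - total // 2
            specs.append(
                CentromereModel(
                    chrom=f"chr{i + 1}",
                    start=start,
                    end=start + total,
                    model=self.cen_model,
                    protected_width=self.protected_width,
                    cde_lengths=self.cde_lengths,
                )
            )
        return specs

    def methylation_params(self) -> MethylationParams:
        return MethylationParams(self.p_meth_accessible, self.p_meth_protected)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    species: tuple[SpeciesBlock, ...] = ()
    calling: CallingParams = field(default_factory=CallingParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    flank: int = 1000
    max_size: int = 400
    nuc_len: int = 147
    linker_mean: float = 20.0
    linker_sd: float = 10.0
    rupture_conditions: tuple[RuptureGenParams, ...] = ()
    rupture_compare: tuple[str, str] | None = None
    distance_blocks: tuple[tuple[str, DistanceGenParams], ...] = ()
    geometry_tol: float = 100.0

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")


def _species_from_dict(d: dict) -> SpeciesBlock:
    d = dict(d)
    if "protected_width" in d and isinstance(d["protected_width"], list):
        d["protected_width"] = tuple(d["protected_width"])
    if "cde_lengths" in d:
        d["cde_lengths"] = tuple(d["cde_lengths"])
    try:
        return SpeciesBlock(**d)
    except TypeError as exc:
        raise ValidationError(f"bad species block: {exc}") from exc


def config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc or {})
    species = tuple(_species_from_dict(s) for s in doc.get("species", []))
    calling = CallingParams(**{
        k: tuple(v) if k == "nucleosomal_range" else v
        for k, v in doc.get("calling", {}).items()
    })
    classify = ClassifyParams(**doc.get("classify", {}))
    ruptures = []
    for block in doc.get("ruptures", []):
        block = dict(block)
        comps = tuple(tuple(c) for c in block.pop("components"))
        ruptures.append(RuptureGenParams(components=comps, **block))
    distances = []
    for block in doc.get("distances", []):
        block = dict(block)
        kind = block.pop("kind")
        distances.append((kind, DistanceGenParams(**block)))
    compare = doc.get("rupture_compare")
    occ = doc.get("occupancy", {})
    chromatin = doc.get("chromatin", {})
    try:
        return PipelineConfig(
            seed=int(doc.get("seed", 0)),
            stages=tuple(doc.get("stages", ALL_STAGES)),
            species=species,
            calling=calling,
            classify=classify,
            flank=int(occ.get("flank", 1000)),
            max_size=int(occ.get("max_size", 400)),
            nuc_len=int(chromatin.get("nuc_len", 147)),
            linker_mean=float(chromatin.get("linker_mean", 20.0)),
            linker_sd=float(chromatin.get("linker_sd", 10.0)),
            rupture_conditions=tuple(ruptures),
            rupture_compare=tuple(compare) if compare else None,
            distance_blocks=tuple(distances),
            geometry_tol=float(doc.get("geometry", {}).get("tol", 100.0)),
        )
    except (TypeError, KeyError) as exc:
        raise ValidationError(f"bad pipeline config: {exc}") from exc


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is not None and not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return config_from_dict(doc or {})


def default_demo_config(seed: int = 0) -> PipelineConfig:
    """A small end-to-end demonstration configuration.

    Two synthetic species mirror the study organisms: a K. marxianus-like
    genome with a 227-bp single protected centromeric block and an
    S. cerevisiae-like genome with a 165-bp block. Rupture conditions mirror
    the untreated (bimodal) and nuclease-treated (unimodal, weaker) samples;
    distance blocks mirror the inter-kinetochore (median 420 nm) and
    doublet-length (median 375 nm) measurements.
    """
    species = (
        SpeciesBlock(name="kmx", protected_width=227, cde_lengths=(8, 165, 25), n_fibers=250,
                     n_chrom=4, chrom_length=30_000),
        SpeciesBlock(name="scer", protected_width=165, cde_lengths=(8, 84, 25), n_fibers=250,
                     n_chrom=4, chrom_length=30_000),
    )
    ruptures = (
        RuptureGenParams(
            components=((0.6, 6.2, 1.5), (0.4, 10.2, 1.5)),
            censor_fraction=0.15,
            n_events=200,
            seed=seed * 97 + 1,
            condition="untreated",
        ),
        RuptureGenParams(
            components=((1.0, 6.4, 1.5),),
            censor_fraction=0.15,
            n_events=200,
            seed=seed * 97 + 2,
            condition="benzonase",
        ),
    )
    distances = (
        ("inter_kt", DistanceGenParams(true_median=420.0, log_sd=0.3, n=274, seed=seed * 97 + 3)),
        ("doublet_length", DistanceGenParams(true_median=375.0, log_sd=0.15, n=31, seed=seed * 97 + 4)),
    )
    return PipelineConfig(
        seed=seed,
        species=species,
        rupture_conditions=ruptures,
        rupture_compare=("untreated", "benzonase"),
        distance_blocks=distances,
    )
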