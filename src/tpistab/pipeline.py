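"""Pipeline orchestration: configuration, model-candidate bookkeeping, reports.

Thin glue over the library modules: parse a TOML config, run the requested
stage (AUC fit + model selection, melt fit, structure comparison, parameter
calculators), and write tab-delimited tables whose header comments record
the package version, the seed and a hash of the configuration, so a report
can always be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    ResidueCounts,
    molar_extinction_280,
    molecular_weight,
    partial_specific_volume,
)
from .fitting import FitResult, ModelChoice, ModelSpec, fit_model, select_model
from .melt import fit_two_state, read_melt_table
from .sedeq import HomogeneousModel, RadialScan, ReversibleModel
from .solution import SolutionRecipe, buffer_density
from .structure import (
    Selection,
    all_chain_pair_ca_rmsd,
    build_ca_mapping,
    ca_rmsd,
    contact_distances,
    proline_fraction,
    read_structure,
    residue_displacement,
    segment_hydrophobicity,
)
from .synth import (
    StudyDesign,
    default_melt_truth,
    generate_auc_dataset,
    generate_melt_curve,
    synthetic_reference_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "parse_model_label",
    "run_auc_analysis",
    "run_melt_analysis",
    "run_structure_comparison",
    "run_params",
]

DEFAULT_CANDIDATES = ("1x", "2x", "4x")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline settings (all stages optional)."""

    seed: int = 0
    outdir: str = "tpistab-out"
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    truth: str = "2x"
    scan_paths: tuple[str, ...] = ()
    melt_path: str | None = None
    structure_apo: str | None = None
    structure_bound: str | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = dict(self.raw)
        payload.setdefault("seed", self.seed)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Read a TOML config file into a PipelineConfig."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    for key in ("scan_paths", "melt_path", "structure_apo", "structure_bound"):
        value = raw.get(key)
        if isinstance(value, str) and not Path(value).exists():
            raise FileNotFoundError(f"config path {key} = {value!r} does not exist")
        if isinstance(value, (list, tuple)):
            for p in value:
                if not Path(p).exists():
                    raise FileNotFoundError(f"config path in {key}: {p!r} does not exist")
    design = StudyDesign(**raw.get("design", {}))
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        outdir=raw.get("outdir", "tpistab-out"),
        candidates=tuple(raw.get("candidates", DEFAULT_CANDIDATES)),
        truth=raw.get("truth", "2x"),
        scan_paths=tuple(raw.get("scan_paths", ())),
        melt_path=raw.get("melt_path"),
        structure_apo=raw.get("structure_apo"),
        structure_bound=raw.get("structure_bound"),
        design=design,
        raw=raw,
    )


def parse_model_label(label: str, monomer_mass: float) -> ModelSpec:
    """Turn a label like ``2x``, ``2x-freeM`` or ``1x-2x`` into a ModelSpec."""
    label = label.strip()
    if "-" in label and label.endswith("freeM"):
        n = int(label.split("x")[0])
        return ModelSpec("homogeneous", n, monomer_mass, free_mass=True)
    if label.count("x") == 2:           # reversible 1x-nx
        left, right = label.split("-")
        if left != "1x":
            raise ValueError(f"reversible labels look like 1x-2x, got {label!r}")
        return ModelSpec("reversible", int(right[:-1]), monomer_mass)
    return ModelSpec("homogeneous", int(label[:-1]), monomer_mass)


def _meta(config: PipelineConfig) -> dict:
    return {"version": __version__, "seed": config.seed,
            "config": config.config_hash()}


def _write_table(df: pd.DataFrame, path: Path, meta: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_scan_file(path, design: StudyDesign, speed_rpm: float) -> RadialScan:
    data = np.loadtxt(path, comments="#", delimiter=None)
    return RadialScan(radii_cm=data[:, 0], absorbance=data[:, 1],
                      rotor=design.rotor(speed_rpm))


def run_auc_analysis(config: PipelineConfig,
                     scans: Sequence[RadialScan] | None = None,
                     precomputed: Sequence[FitResult] | None = None
                     ) -> ModelChoice:
    """Fit the candidate models, select one, and write the report tables.

    Scans come from (in order of precedence) the ``scans`` argument, the
    configured scan paths, or the synthetic generator run with the
    configured truth/design/seed.  ``precomputed`` FitResults (e.g. RMS
    values from an external program) skip fitting entirely and go straight
    to selection.
    """
    outdir = Path(config.outdir)
    design = config.design
    if precomputed is not None:
        choice = select_model(list(precomputed))
        rows = [{"model": c.label, "rms": c.rms, "n_params": c.n_params,
                 "selected": c is choice.selected} for c in choice.ranked]
        _write_table(pd.DataFrame(rows), outdir / "auc_fit_table.tsv", _meta(config))
        return choice

    if scans is None:
        if config.scan_paths:
            if len(config.scan_paths) != len(design.speeds_rpm):
                raise ValueError("provide one scan file per configured rotor speed")
            scans = [_read_scan_file(p, design, s)
                     for p, s in zip(config.scan_paths, design.speeds_rpm)]
        else:
            truth_spec = parse_model_label(config.truth, design.monomer_mass)
            if truth_spec.family != "homogeneous":
                truth = ReversibleModel(monomer_mass=design.monomer_mass,
                                        n=truth_spec.n, bottom_conc=0.1, ln_k=0.0)
            else:
                truth = HomogeneousModel(monomer_mass=design.monomer_mass,
                                         n=truth_spec.n)
            scans = generate_auc_dataset(truth, design, seed=config.seed)

    buoyancy = design.buoyancy()
    results = []
    for label in config.candidates:
        spec = parse_model_label(label, design.monomer_mass)
        try:
            results.append(fit_model(scans, spec, buoyancy))
        except Exception as exc:                        # noqa: BLE001
            raise RuntimeError(f"AUC fitting stage failed for model {label}") from exc
    choice = select_model(results)

    rows = []
    for c in choice.ranked:
        rows.append({"model": c.label, "rms": c.rms, "wssq": c.wssq,
                     "n_params": c.n_params, "converged": c.converged,
                     "monomer_mass": c.params.get("monomer_mass"),
                     "ln_k": c.params.get("ln_k"),
                     "selected": c is choice.selected,
                     "notes": "; ".join(choice.rationale.get(c.label, []))})
    _write_table(pd.DataFrame(rows), outdir / "auc_fit_table.tsv", _meta(config))

    res_rows = []
    for c in choice.ranked:
        for scan, res in zip(scans, c.residuals):
            for r, v in zip(scan.radii_cm, res):
                res_rows.append({"model": c.label, "sector": scan.sector,
                                 "radius_cm": r, "residual": v})
    _write_table(pd.DataFrame(res_rows), outdir / "auc_residuals.tsv", _meta(config))
    logger.info("AUC verdict: %s", choice.selected.label)
    return choice


def run_melt_analysis(config: PipelineConfig):
    """Fit the two-state model to a measured or synthetic melt curve."""
    if config.melt_path:
        curve = read_melt_table(config.melt_path)
    else:
        curve = generate_melt_curve(default_melt_truth(),
                                    noise_sd=config.raw.get("melt_noise_sd", 0.0),
                                    seed=config.seed)
    params, rms = fit_two_state(curve)
    df = pd.DataFrame([{"Td_C": params.td_C, "dHvH_kJ_mol": params.dh_vh_kJ_mol,
                        "folded_intercept": params.folded_intercept,
                        "folded_slope": params.folded_slope,
                        "unfolded_intercept": params.unfolded_intercept,
                        "unfolded_slope": params.unfolded_slope, "rms": rms}])
    _write_table(df, Path(config.outdir) / "melt_fit.tsv", _meta(config))
    return params, rms


def run_structure_comparison(config: PipelineConfig,
                             displacement_residues: Sequence[int] = (143, 175),
                             contact_cutoff: float = 3.5) -> dict:
    """Chain-pair RMSDs, marker-residue displacements and ligand contacts.

    Uses the configured structure files when given, otherwise the synthetic
    reference pair.  Returns the report as a dict of DataFrames and writes
    each as a TSV.
    """
    if config.structure_apo and config.structure_bound:
        apo = read_structure(config.structure_apo)
        bound = read_structure(config.structure_bound)
    else:
        apo, bound = synthetic_reference_pair()
    if not set(apo.chains) & set(bound.chains):
        raise ValueError(f"no common chain ids between models: "
                         f"{apo.chains} vs {bound.chains}")
    outdir = Path(config.outdir)
    meta = _meta(config)

    pair_rows = all_chain_pair_ca_rmsd(apo, bound)
    pairs = pd.DataFrame(pair_rows)
    _write_table(pairs, outdir / "chain_pair_rmsd.tsv", meta)

    disp_rows = []
    for chain in sorted(set(apo.chains) & set(bound.chains)):
        mapping = build_ca_mapping(apo, bound, chain, chain)
        sup = ca_rmsd(apo, bound, mapping).superposition
        for res in displacement_residues:
            disp_rows.append({"chain": chain, "res_seq": res,
                              "displacement_A": residue_displacement(
                                  apo, bound, sup, chain, res)})
    disp = pd.DataFrame(disp_rows)
    _write_table(disp, outdir / "residue_displacements.tsv", meta)

    contact_rows = []
    for chain, res_seq, res_name in bound.hetero_groups():
        lig_sel = Selection(chain=chain, res_seq=res_seq, res_name=res_name)
        prot_sel = Selection(chain=chain, hetero=False)
        for c in contact_distances(bound, lig_sel, prot_sel, cutoff=contact_cutoff):
            contact_rows.append({
                "chain": chain, "ligand": res_name,
                "protein_res": f"{c.protein_atom[2]}{c.protein_atom[1]}",
                "protein_atom": c.protein_atom[3],
                "ligand_atom": c.ligand_atom[3],
                "distance_A": c.distance})
    contacts = pd.DataFrame(contact_rows)
    _write_table(contacts, outdir / "ligand_contacts.tsv", meta)

    seqs = {ch: apo.polymer_sequence(ch) for ch in apo.chains}
    seq_rows = [{"chain": ch, "length": len(s),
                 "proline_pct": proline_fraction(s)} for ch, s in seqs.items() if s]
    _write_table(pd.DataFrame(seq_rows), outdir / "sequence_metrics.tsv", meta)

    return {"chain_pairs": pairs, "displacements": disp, "contacts": contacts,
            "sequences": pd.DataFrame(seq_rows)}


def run_params(config: PipelineConfig, sequence: str | None = None,
               tag: str = "", recipe: SolutionRecipe | None = None) -> dict:
    """Composition and solution calculators: MW, eps280, vbar, buffer density."""
    if sequence is None:
        from .synth import SYNTHETIC_TATPI_ORF, SYNTHETIC_TATPI_TAG
        sequence, tag = SYNTHETIC_TATPI_ORF, SYNTHETIC_TATPI_TAG
    counts = ResidueCounts.from_sequence(sequence, tag=tag)
    if recipe is None:
        recipe = SolutionRecipe(components=[("Tris-HCl", 0.020), ("NaCl", 0.200)],
                                temperature_K=config.design.temperature_K, pH=7.5)
    out = {
        "molecular_weight_Da": molecular_weight(counts),
        "eps280_M_cm": molar_extinction_280(counts),
        "vbar_cm3_g": partial_specific_volume(counts, recipe.temperature_K),
        "buffer_density_g_cm3": buffer_density(recipe),
        "proline_pct": proline_fraction(sequence),
        "helix5_hydrophobicity": segment_hydrophobicity(sequence[105:115])
        if len(sequence) >= 115 else None,
    }
    _write_table(pd.DataFrame([out]), Path(config.outdir) / "parameters.tsv",
                 _meta(config))
    return out
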