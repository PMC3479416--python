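"""End-to-end analysis: structures -> classified chi vectors -> comparisons.

The pipeline walks a manifest of cases.  Each case is one bound complex
(receptor chains + ligand chains) with zero, one or two unbound monomer
structures.  Per case:

1. the complex and each extracted monomer get Shrake-Rupley SASA;
2. each bound residue is classified interface / non-interface surface /
   excluded from its relative SASA and its SASA loss upon binding;
3. unbound residues are mapped to their bound partners by global sequence
   alignment and inherit the bound classification (the surface rule also
   requires >= 25% relative SASA in the unbound state);
4. chi vectors are computed for every classified residue; residues with
   missing side-chain atoms are logged and excluded.

Classified records pool across all cases per residue type into four
categories (interface/non-interface x bound/unbound); the analysis then
runs the offset-averaged comparison for the four category pairs over a
spacing scan and detects each pair's critical spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sasa as sasa_mod
from .compare import CRITICAL_R, averaged_comparison, critical_spacing
from .correspondence import align_global, map_residues
from .dihedrals import CHI_ATOMS, CHI_COUNT, residue_chi_vector
from .sasa import SurfaceClass, classify_surface, delta_sasa, relative_sasa, \
    residue_sasa, shrake_rupley
from .structure_io import Structure, extract_monomer, read_structure, \
    residue_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig", "CaseEntry", "ResidueRecord", "read_manifest",
    "process_case", "residue_counts", "run_analysis", "AnalysisOutput",
    "write_angle_table", "read_angle_table", "CATEGORY_PAIRS",
]

#: the four comparison designs: (label, (class_x, state_x), (class_y, state_y))
CATEGORY_PAIRS = (
    ("interface_bound_vs_unbound",
     ("interface", "bound"), ("interface", "unbound")),
    ("non_interface_bound_vs_unbound",
     ("non_interface_surface", "bound"), ("non_interface_surface", "unbound")),
    ("non_interface_vs_interface_unbound",
     ("non_interface_surface", "unbound"), ("interface", "unbound")),
    ("non_interface_vs_interface_bound",
     ("non_interface_surface", "bound"), ("interface", "bound")),
)

MANIFEST_COLUMNS = [
    "case_id", "complex_pdb", "receptor_chains", "ligand_chains",
    "unbound_receptor_pdb", "unbound_receptor_chains",
    "unbound_ligand_pdb", "unbound_ligand_chains",
]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis."""
    spacings: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    n_repeats: int = 100
    seed: int = 0
    probe: float = sasa_mod.DEFAULT_PROBE
    n_points: int = sasa_mod.DEFAULT_N_POINTS
    surface_threshold: float = sasa_mod.REL_SASA_SURFACE
    interface_threshold: float = sasa_mod.DSASA_INTERFACE
    critical_r: float = CRITICAL_R
    min_samples: int = 20


@dataclass
class CaseEntry:
    case_id: str
    complex_pdb: str
    receptor_chains: str
    ligand_chains: str
    unbound_receptor_pdb: str | None = None
    unbound_receptor_chains: str | None = None
    unbound_ligand_pdb: str | None = None
    unbound_ligand_chains: str | None = None


@dataclass
class ResidueRecord:
    case_id: str
    side: str       # receptor | ligand
    state: str      # bound | unbound
    chain_id: str
    seq_num: int
    icode: str
    res_type: str
    surface_class: str  # interface | non_interface_surface | excluded
    angles: tuple[float, ...] | None  # None = missing chi atoms / no chis


def read_manifest(path) -> list[CaseEntry]:
    """Read the tab-separated case manifest; empty fields become None."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(CaseEntry(**{
            col: (row[col] if row[col] != "" else None)
            if col.startswith("unbound") else row[col]
            for col in MANIFEST_COLUMNS}))
    return entries


def _per_residue_sasa(structure: Structure, config: AnalysisConfig) -> dict:
    per_atom = shrake_rupley(structure, probe=config.probe,
                             n_points=config.n_points)
    return {rec.residue_key: rec for rec in residue_sasa(per_atom, structure)}


def _classify_monomer(complex_structure: Structure, chains: str,
                      complex_sasa: dict, config: AnalysisConfig
                      ) -> tuple[Structure, dict, dict]:
    """Bound-side classification of one monomer within a complex.

    Returns (monomer structure, per-residue SurfaceClass before the unbound
    check, per-residue bound relative SASA).
    """
    monomer = extract_monomer(complex_structure, set(chains))
    mono_sasa = _per_residue_sasa(monomer, config)
    classes: dict = {}
    rel_bound: dict = {}
    for res in monomer.residues:
        if not res.is_standard:
            classes[res.key] = None  # non-standard: excluded downstream
            continue
        rec = mono_sasa[res.key]
        rel = relative_sasa(rec.abs_sasa, res.res_type)
        rel_bound[res.key] = rel
        ds = delta_sasa(rec.abs_sasa, complex_sasa[res.key].abs_sasa)
        classes[res.key] = (rel, ds)
    return monomer, classes, rel_bound


def _side_records(case: CaseEntry, side: str, complex_structure: Structure,
                  complex_sasa: dict, chains: str,
                  unbound_pdb: str | None, unbound_chains: str | None,
                  config: AnalysisConfig, exclusions: list) -> list[ResidueRecord]:
    records: list[ResidueRecord] = []
    monomer, raw, _ = _classify_monomer(complex_structure, chains,
                                        complex_sasa, config)

    unbound = None
    rel_unbound_by_bound_key: dict = {}
    bound_to_unbound: dict = {}
    if unbound_pdb is not None:
        unbound = read_structure(Path(unbound_pdb).read_text(),
                                 set(unbound_chains),
                                 structure_id=f"{case.case_id}:{side}:unbound")
        unb_sasa = _per_residue_sasa(unbound, config)
        # chains correspond positionally: bound chain i <-> unbound chain i
        for b_chain, u_chain in zip(chains, unbound_chains):
            seq_b, _ = residue_sequence(monomer, b_chain)
            seq_u, _ = residue_sequence(unbound, u_chain)
            aln = align_global(seq_b, seq_u)
            corr = map_residues(aln, monomer, b_chain, unbound, u_chain)
            for b_key, u_key in corr.pairs:
                bound_to_unbound[b_key] = u_key
                u_res = unbound.residue(u_key)
                if u_res.is_standard:
                    rel_unbound_by_bound_key[b_key] = relative_sasa(
                        unb_sasa[u_key].abs_sasa, u_res.res_type)

    for res in monomer.residues:
        if raw.get(res.key) is None:
            exclusions.append((case.case_id, side, res.key, "non_standard"))
            continue
        rel_bound, ds = raw[res.key]
        rel_unb = rel_unbound_by_bound_key.get(res.key) if unbound else None
        cls = classify_surface(rel_bound, rel_unb, ds,
                               config.surface_threshold,
                               config.interface_threshold)
        chi = residue_chi_vector(res)
        if res.res_type in CHI_ATOMS and chi is None \
                and cls is not SurfaceClass.EXCLUDED:
            exclusions.append((case.case_id, side, res.key,
                               "missing_chi_atoms"))
        records.append(ResidueRecord(
            case.case_id, side, "bound", res.chain_id, res.seq_num, res.icode,
            res.res_type, cls.value,
            chi.angles if chi is not None else None))
        # the mapped unbound residue inherits the bound classification
        u_key = bound_to_unbound.get(res.key)
        if u_key is not None:
            u_res = unbound.residue(u_key)
            u_chi = residue_chi_vector(u_res)
            if u_res.res_type in CHI_ATOMS and u_chi is None \
                    and cls is not SurfaceClass.EXCLUDED:
                exclusions.append((case.case_id, side, u_key,
                                   "missing_chi_atoms_unbound"))
            records.append(ResidueRecord(
                case.case_id, side, "unbound", u_res.chain_id, u_res.seq_num,
                u_res.icode, u_res.res_type, cls.value,
                u_chi.angles if u_chi is not None else None))
    return records


def process_case(case: CaseEntry, config: AnalysisConfig | None = None,
                 exclusions: list | None = None) -> list[ResidueRecord]:
    """All classified residue records of one bound/unbound case.

    ``exclusions``, when given, collects (case_id, side, residue_key,
    reason) tuples for every residue left out of the angle pools.
    """
    config = config or AnalysisConfig()
    if exclusions is None:
        exclusions = []
    complex_structure = read_structure(
        Path(case.complex_pdb).read_text(),
        set(case.receptor_chains) | set(case.ligand_chains),
        structure_id=case.case_id)
    complex_sasa = _per_residue_sasa(complex_structure, config)
    records = []
    for side, chains, u_pdb, u_chains in (
            ("receptor", case.receptor_chains,
             case.unbound_receptor_pdb, case.unbound_receptor_chains),
            ("ligand", case.ligand_chains,
             case.unbound_ligand_pdb, case.unbound_ligand_chains)):
        records.extend(_side_records(case, side, complex_structure,
                                     complex_sasa, chains, u_pdb, u_chains,
                                     config, exclusions))
    return records


def process_manifest(entries: list[CaseEntry],
                     config: AnalysisConfig | None = None
                     ) -> tuple[list[ResidueRecord], list]:
    """Process every case; unreadable cases are logged and skipped."""
    config = config or AnalysisConfig()
    records: list[ResidueRecord] = []
    exclusions: list = []
    for case in entries:
        try:
            records.extend(process_case(case, config, exclusions))
        except (OSError, ValueError) as exc:
            logger.error("case %s skipped: %s", case.case_id, exc)
    return records, exclusions


def residue_counts(records: list[ResidueRecord]) -> pd.DataFrame:
    """Surface-residue counts per residue type, U/B x interface/non-interface.

    18 chi-bearing residue types as rows; columns ``interface_U``,
    ``interface_B``, ``non_interface_U``, ``non_interface_B``.
    """
    index = list(CHI_ATOMS)
    counts = pd.DataFrame(0, index=index, columns=[
        "interface_U", "interface_B", "non_interface_U", "non_interface_B"])
    counts.index.name = "res_type"
    for rec in records:
        if rec.res_type not in CHI_COUNT:
            continue
        if rec.surface_class == "interface":
            col = "interface_U" if rec.state == "unbound" else "interface_B"
        elif rec.surface_class == "non_interface_surface":
            col = ("non_interface_U" if rec.state == "unbound"
                   else "non_interface_B")
        else:
            continue
        counts.loc[rec.res_type, col] += 1
    return counts


@dataclass
class AnalysisOutput:
    comparisons: pd.DataFrame
    critical: pd.DataFrame
    skipped: pd.DataFrame


def _pool_angles(records: list[ResidueRecord]) -> dict:
    pools: dict[tuple[str, str, str], list] = {}
    for rec in records:
        if rec.angles is None or rec.surface_class == "excluded":
            continue
        pools.setdefault((rec.res_type, rec.surface_class, rec.state),
                         []).append(rec.angles)
    return {k: np.asarray(v, dtype=float) for k, v in pools.items()}


def run_analysis(records: list[ResidueRecord],
                 config: AnalysisConfig | None = None) -> AnalysisOutput:
    """Four-category comparison tables and critical spacings from records.

    Deterministic for a fixed config seed: each (residue type, category
    pair, spacing) cell draws its random split origins from an independent
    generator keyed on the seed and the cell's identity, so results do not
    depend on iteration order.
    """
    config = config or AnalysisConfig()
    pools = _pool_angles(records)
    res_types = sorted({rt for rt, _, _ in pools}, key=list(CHI_ATOMS).index)
    rows, skipped = [], []
    critical_rows = []
    for rt_idx, res_type in enumerate(res_types):
        for pair_idx, (label, (cls_x, st_x), (cls_y, st_y)) in enumerate(
                CATEGORY_PAIRS):
            x = pools.get((res_type, cls_x, st_x))
            y = pools.get((res_type, cls_y, st_y))
            n_x = 0 if x is None else len(x)
            n_y = 0 if y is None else len(y)
            if n_x < config.min_samples or n_y < config.min_samples:
                skipped.append({"res_type": res_type, "category_pair": label,
                                "n_x": n_x, "n_y": n_y,
                                "reason": "below_min_samples"})
                continue
            series = {}
            for spacing in config.spacings:
                rng = np.random.default_rng(
                    [config.seed, rt_idx, pair_idx, int(round(spacing * 10))])
                res = averaged_comparison(
                    x, y, res_type, spacing, n_repeats=config.n_repeats,
                    rng=rng, category_pair=label)
                series[spacing] = res.mean_r
                rows.append({
                    "res_type": res_type, "category_pair": label,
                    "spacing": spacing, "mean_r": res.mean_r,
                    "sd_r": res.sd_r, "mean_d": res.mean_d, "sd_d": res.sd_d,
                    "p_value": res.p_value, "m": res.m, "n_x": res.n_x,
                    "n_y": res.n_y, "n_repeats": res.n_repeats,
                    "n_undefined": res.n_undefined})
            critical_rows.append({
                "res_type": res_type, "category_pair": label,
                "critical_spacing": critical_spacing(series,
                                                     config.critical_r)})
    return AnalysisOutput(
        comparisons=pd.DataFrame(rows),
        critical=pd.DataFrame(critical_rows),
        skipped=pd.DataFrame(skipped,
                             columns=["res_type", "category_pair", "n_x",
                                      "n_y", "reason"]),
    )


# ---------------------------------------------------------------------------
# intermediate angle-table format (TSV)

ANGLE_COLUMNS = ["case_id", "side", "state", "chain", "seq_num", "icode",
                 "res_type", "surface_class", "chi1", "chi2", "chi3", "chi4"]


def write_angle_table(records: list[ResidueRecord], path) -> None:
    """TSV export of residue records; chi columns blank where absent."""
    rows = []
    for rec in records:
        row = {"case_id": rec.case_id, "side": rec.side, "state": rec.state,
               "chain": rec.chain_id, "seq_num": rec.seq_num,
               "icode": rec.icode, "res_type": rec.res_type,
               "surface_class": rec.surface_class}
        for i in range(4):
            row[f"chi{i + 1}"] = (
                f"{rec.angles[i]:.4f}"
                if rec.angles is not None and i < len(rec.angles) else "")
        rows.append(row)
    pd.DataFrame(rows, columns=ANGLE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def read_angle_table(path) -> list[ResidueRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        chis = [row[f"chi{i + 1}"] for i in range(4)]
        chis = [float(c) for c in chis if c != ""]
        records.append(ResidueRecord(
            case_id=row["case_id"], side=row["side"], state=row["state"],
            chain_id=row["chain"], seq_num=int(row["seq_num"]),
            icode=row["icode"], res_type=row["res_type"],
            surface_class=row["surface_class"],
            angles=tuple(chis) if chis else None))
    return records


def write_analysis(output: AnalysisOutput, out_dir) -> None:
    """Write the comparison, critical-spacing and skipped tables as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    output.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                              float_format="%.4f")
    output.critical.to_csv(out / "critical_spacing.tsv", sep="\t",
                           index=False, float_format="%.4f")
    output.skipped.to_csv(out / "skipped.tsv", sep="\t", index=False)
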