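"""Ligand grafting: transfer ligands from a resolved homolog complex onto a
predicted apo receptor model by rigid superposition, and audit the steric
clashes that downstream restrained minimisation must resolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import AtomSelection, Structure, select
from .geometry import kabsch_fit

log = logging.getLogger(__name__)


@dataclass
class ClashReport:
    """Protein/ligand heavy-atom pairs closer than the clash threshold."""

    pairs: pd.DataFrame   # protein_atom, ligand_atom, distance
    threshold: float

    @property
    def count(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        out = self.pairs.copy()
        out["threshold"] = self.threshold
        out.to_csv(path, index=False)


def _resolve(structure: Structure, sel) -> AtomSelection:
    if isinstance(sel, AtomSelection):
        return sel
    return select(structure, sel)


def graft_ligands(
    receptor: Structure,
    template_complex: Structure,
    ligand_resnames: list[str],
    receptor_align_sel,
    template_align_sel,
) -> tuple[Structure, float]:
    """Superpose the template onto the receptor and carry its ligands over.

    ``receptor_align_sel`` / ``template_align_sel`` are matched, equal-length
    selections (e.g. shared-residue CA atoms); automatic sequence-based
    pairing is deliberately not attempted so the alignment stays auditable
    between non-identical sequences.  Returns the merged structure
    (receptor atoms followed by the transferred ligand residues) and the
    alignment fit RMSD in Angstrom.
    """
    rec_sel = _resolve(receptor, receptor_align_sel)
    tpl_sel = _resolve(template_complex, template_align_sel)
    if len(rec_sel) != len(tpl_sel):
        raise ValueError(
            f"alignment selections differ in length: receptor {len(rec_sel)} "
            f"vs template {len(tpl_sel)}")
    lig_mask = np.isin(template_complex.resnames, list(ligand_resnames))
    if not lig_mask.any():
        missing = set(ligand_resnames) - set(template_complex.resnames)
        raise ValueError(f"ligand residues {sorted(missing)} absent from template")

    tf, fit_rmsd = kabsch_fit(
        template_complex.coords[tpl_sel.indices],
        receptor.coords[rec_sel.indices],
    )
    log.info("template-to-receptor fit RMSD: %.3f A over %d atom pairs",
             fit_rmsd, len(rec_sel))

    lig_idx = np.nonzero(lig_mask)[0]
    ligand = template_complex.subset(lig_idx)
    ligand = ligand.with_coords(tf.apply(ligand.coords))

    merged = Structure(
        names=np.concatenate([receptor.names, ligand.names]),
        elements=np.concatenate([receptor.elements, ligand.elements]),
        resnames=np.concatenate([receptor.resnames, ligand.resnames]),
        resids=np.concatenate([receptor.resids, ligand.resids]),
        chainids=np.concatenate([receptor.chainids, ligand.chainids]),
        coords=np.vstack([receptor.coords, ligand.coords]),
        box=receptor.box,
    )
    return merged, fit_rmsd


def clash_report(
    complex_structure: Structure,
    ligand_resnames: list[str],
    threshold: float = 2.0,
) -> ClashReport:
    """All protein-heavy / ligand-heavy pairs closer than the threshold.

    Pairs are sorted ascending by distance.  The default 2.0 A flags
    overlaps that restrained energy minimisation (out of scope here) would
    need to relax.
    """
    s = complex_structure
    lig_mask = np.isin(s.resnames, list(ligand_resnames))
    if not lig_mask.any():
        raise ValueError(f"no ligand residues {ligand_resnames} in structure")
    heavy = s.heavy_mask()
    lig_idx = np.nonzero(lig_mask & heavy)[0]
    prot_idx = np.nonzero(~lig_mask & heavy)[0]
    if len(prot_idx) == 0:
        raise ValueError("structure has no protein heavy atoms")

    d = cdist(s.coords[prot_idx], s.coords[lig_idx])
    keys = s.residue_keys()
    rows = []
    for i, j in zip(*np.nonzero(d < threshold)):
        pi, lj = prot_idx[i], lig_idx[j]
        rows.append({
            "protein_atom": f"{keys[pi]}:{s.names[pi]}",
            "ligand_atom": f"{keys[lj]}:{s.names[lj]}",
            "distance": float(d[i, j]),
        })
    pairs = pd.DataFrame(rows, columns=["protein_atom", "ligand_atom", "distance"])
    pairs = pairs.sort_values("distance", kind="mergesort").reset_index(drop=True)
    return ClashReport(pairs=pairs, threshold=threshold)
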