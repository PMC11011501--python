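"""Per-residue ligand contact frequencies over pooled trajectories.

A residue is "in contact" in a frame iff its minimum heavy-atom distance to
the ligand's heavy atoms is within the cutoff (default 3.0 A, boundary
inclusive).  Frequencies are pooled over all supplied trajectory copies;
a per-copy breakdown is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AtomSelection, Structure, Trajectory, select


@dataclass
class ContactProfile:
    """Contact frequency per residue key ('chain:RESNAME:resid')."""

    entries: pd.DataFrame       # columns: residue_key, resid, frequency, n_frames_in_contact
    cutoff: float
    ligand_expression: str
    n_frames: int
    per_copy: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        f = self.entries["frequency"].to_numpy()
        if len(f) and (f.min() < 0 or f.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")

    def frequency(self, residue_key: str) -> float:
        row = self.entries[self.entries["residue_key"] == residue_key]
        if row.empty:
            raise KeyError(residue_key)
        return float(row["frequency"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.entries.copy()
        out["cutoff"] = self.cutoff
        out.to_csv(path, index=False)


def _resolve(structure: Structure, sel) -> AtomSelection:
    if isinstance(sel, AtomSelection):
        return sel
    return select(structure, sel)


def contact_frequency(
    trajs: Trajectory | list[Trajectory],
    ligand_sel,
    cutoff: float = 3.0,
    residue_scope=None,
) -> ContactProfile:
    """Fraction of pooled frames in which each residue touches the ligand.

    Parameters
    ----------
    trajs : one Trajectory or a list of copies sharing a topology.
    ligand_sel : selection expression or AtomSelection for the ligand;
        hydrogens are dropped, a hydrogen-only selection is an error.
    cutoff : contact distance in Angstrom, boundary inclusive.
    residue_scope : selection restricting which residues are profiled;
        defaults to every non-ligand residue.  Must be non-empty.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories supplied")
    top = trajs[0].topology
    heavy = top.heavy_mask()

    lig = _resolve(top, ligand_sel)
    if len(lig) == 0:
        raise ValueError("ligand selection is empty")
    lig_expr = lig.expression
    lig_idx = lig.indices[heavy[lig.indices]]
    if len(lig_idx) == 0:
        raise ValueError("ligand selection contains only hydrogens")

    if residue_scope is None:
        scope_mask = np.ones(top.n_atoms, dtype=bool)
        scope_mask[lig.indices] = False
        scope = AtomSelection(np.nonzero(scope_mask)[0], "not ligand")
    else:
        scope = _resolve(top, residue_scope)
    if len(scope) == 0:
        raise ValueError("residue scope is empty")
    scope_idx = scope.indices[heavy[scope.indices]]
    if len(scope_idx) == 0:
        raise ValueError("residue scope contains only hydrogens")

    keys = top.residue_keys()
    # group scope atoms by residue, preserving first-appearance order
    groups: dict[str, list[int]] = {}
    for i in scope_idx:
        groups.setdefault(keys[i], []).append(i)

    per_copy_rows = []
    counts = {k: 0 for k in groups}
    total = 0
    for traj in trajs:
        T = traj.n_frames
        lig_xyz = traj.frames[:, lig_idx, :]          # (T, L, 3)
        copy_counts = {}
        for key, atom_ids in groups.items():
            res_xyz = traj.frames[:, atom_ids, :]      # (T, m, 3)
            d2 = np.sum(
                (res_xyz[:, :, None, :] - lig_xyz[:, None, :, :]) ** 2, axis=-1
            )
            in_contact = d2.reshape(T, -1).min(axis=1) <= cutoff * cutoff
            n = int(in_contact.sum())
            counts[key] += n
            copy_counts[key] = n
        total += T
        for key, n in copy_counts.items():
            per_copy_rows.append(
                {"source_id": traj.source_id, "residue_key": key,
                 "frequency": n / T, "n_frames_in_contact": n, "n_frames": T}
            )

    rows = []
    for key, n in counts.items():
        resid = int(key.rsplit(":", 1)[1])
        rows.append({"residue_key": key, "resid": resid,
                     "frequency": n / total, "n_frames_in_contact": n})
    entries = pd.DataFrame(rows, columns=["residue_key", "resid", "frequency",
                                          "n_frames_in_contact"])
    return ContactProfile(
        entries=entries, cutoff=cutoff, ligand_expression=lig_expr,
        n_frames=total, per_copy=pd.DataFrame(per_copy_rows),
    )


def rank_contacts(profile: ContactProfile, min_frequency: float) -> ContactProfile:
    """Entries with frequency strictly above ``min_frequency``.

    Sorted descending by frequency; ties broken by ascending residue id.
    """
    kept = profile.entries[profile.entries["frequency"] > min_frequency]
    kept = kept.sort_values(
        ["frequency", "resid"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ContactProfile(
        entries=kept, cutoff=profile.cutoff,
        ligand_expression=profile.ligand_expression,
        n_frames=profile.n_frames, per_copy=profile.per_copy,
    )
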