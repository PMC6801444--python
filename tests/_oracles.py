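"""Independent brute-force oracles, written as plain loops from first
principles, for checking the vectorized implementations."""

import numpy as np

from chiralmem import geometry as geo


def rodrigues(v, axis, angle_rad):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle_rad) + np.cross(axis, v) * np.sin(angle_rad)
            + axis * np.dot(axis, v) * (1 - np.cos(angle_rad)))


def side_label(point, frame, chirality, eps=1e-6):
    """Side of the dividing plane, from the vertical velocity of the
    helix-surface point at the lipid's azimuth under the chirality's
    rotation sense."""
    rel = np.asarray(point, float) - frame.centroid
    q = rel - np.dot(rel, frame.axis) * frame.axis
    sense = -1.0 if chirality == "L" else 1.0
    delta = rodrigues(q, frame.axis, sense * eps) - q
    if delta[2] == 0.0:
        return geo.ASCENDING
    return geo.DESCENDING if delta[2] < 0 else geo.ASCENDING


def lipid_atom_table(lipid):
    """[(class, xyz)] with class in {head, c2, tail}."""
    rows = []
    for xyz in np.atleast_2d(lipid.head_atoms):
        rows.append(("head", np.asarray(xyz, float)))
    rows.append(("c2", np.asarray(lipid.c2_atom, float)))
    for xyz in np.atleast_2d(lipid.tail_atoms):
        rows.append(("tail", np.asarray(xyz, float)))
    return rows


def contact_analysis(frame, policy):
    """Exhaustive re-derivation of ambient set, side labels, classified
    contact counts, S_rot, Trp-head contacts and the side census."""
    pep = frame.peptide
    pep_atoms = pep.heavy_coords()

    ambient = []
    for lipid in frame.lipids:
        dmin = min(np.linalg.norm(p - xyz)
                   for p in pep_atoms for _, xyz in lipid_atom_table(lipid))
        if dmin <= policy.ambient_cutoff:
            ambient.append(lipid.lipid_id)

    helix = geo.helix_axis(pep.ca_coords())
    sides = {}
    for lipid in frame.lipids:
        if lipid.lipid_id not in ambient:
            continue
        ref = (np.asarray(lipid.c2_atom, float) if policy.side_basis == "c2"
               else np.mean([xyz for _, xyz in lipid_atom_table(lipid)], axis=0))
        sides[lipid.lipid_id] = side_label(ref, helix, pep.chirality)

    counts = {"dp": 0, "dh": 0, "ap": 0, "ah": 0}
    for lipid in frame.lipids:
        if lipid.lipid_id not in sides:
            continue
        table = lipid_atom_table(lipid)
        for res in pep.residue_indices():
            res_atoms = pep.residue_heavy_coords(res)
            dmin = min(np.linalg.norm(a - xyz) for a in res_atoms
                       for _, xyz in table)
            if dmin > policy.contact_cutoff:
                continue
            ht = [(c, xyz) for c, xyz in table if c != "c2"]
            nearest = min(ht, key=lambda row: min(
                np.linalg.norm(a - row[1]) for a in res_atoms))[0]
            atom_type = "p" if nearest == "head" else "h"
            res_type = ("p" if pep.polarity_class[res] == "polar_charged" else "h")
            if policy.mixed_mode == "strict" and atom_type != res_type:
                continue
            side = "d" if sides[lipid.lipid_id] == geo.DESCENDING else "a"
            counts[side + atom_type] += 1
    w_dp, w_dh, w_ah, w_ap = policy.weights
    s_rot = (w_dp * counts["dp"] + w_dh * counts["dh"]
             + w_ah * counts["ah"] + w_ap * counts["ap"])

    trp = 0
    trp_atoms = pep.residue_heavy_coords(pep.trp_index)
    for lipid in frame.lipids:
        dmin = min(np.linalg.norm(a - xyz) for a in trp_atoms
                   for c, xyz in lipid_atom_table(lipid) if c == "head")
        if dmin <= policy.contact_cutoff:
            trp += 1

    n_des = sum(1 for s in sides.values() if s == geo.DESCENDING)
    n_asc = len(sides) - n_des
    return {"ambient": sorted(ambient), "sides": sides, "counts": counts,
            "s_rot": s_rot, "trp_head": trp, "n_des": n_des, "n_asc": n_asc}
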