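"""Residue-lipid contact statistics around an adsorbing helix.

The analysis restricts itself to *ambient* lipids -- those whose nearest
heavy atom lies within 0.3 nm of the peptide -- and classifies every
residue-lipid contact (any heavy-atom pair within 0.5 nm) along two axes:

* side: descending (d) or ascending (a), from the lipid's position
  relative to the chirality-dependent rotation sense of the helix
  (labeled by the chiral C2 carbon of the lipid, or its center of mass);
* interaction type: hydrophobic (h, lipid tail atoms) or polar (p, lipid
  head-group atoms).

The four counts combine into the rotational driving-force score

    S_rot = w_dp N_dp + w_dh N_dh + w_ah N_ah + w_ap N_ap,

whose shipped default weights (+1, +1, -1, -1) encode that contacts on the
descending side drive the adsorption rotation while ascending-side
contacts impede it.  The weight values are configuration, not constants of
nature, and every result records the weights used.

Also here: Trp-head-group contact counting (at most one contact per
Trp-lipid pair), the descending/ascending lipid census
``delta_n = n_des - n_asc``, and debounced side-switch counting over
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .geometry import ASCENDING, DESCENDING


class LipidPartitionError(ValueError):
    """A lipid does not declare both head and tail atoms."""


@dataclass
class ContactPolicy:
    """Cutoffs, atom-class partitions and score weights.

    Distances in nm; ``weights`` ordered (w_dp, w_dh, w_ah, w_ap).
    ``mixed_mode`` controls contacts that pair a nonpolar residue with a
    head atom or a polar residue with a tail atom: ``"by_lipid_atom"``
    classifies by the lipid atom (head -> polar, tail -> hydrophobic);
    ``"strict"`` counts only (nonpolar, tail) and (polar_charged, head)
    pairs.  ``side_basis`` picks the lipid reference point for side
    labeling: the chiral carbon C2 or the lipid center of mass.
    """

    ambient_cutoff: float = 0.3
    contact_cutoff: float = 0.5
    weights: tuple = (1.0, 1.0, -1.0, -1.0)
    mixed_mode: str = "by_lipid_atom"
    side_basis: str = "c2"
    debounce: int = 5

    def __post_init__(self):
        if self.ambient_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.mixed_mode not in ("by_lipid_atom", "strict"):
            raise ValueError(f"unknown mixed_mode {self.mixed_mode!r}")
        if self.side_basis not in ("c2", "com"):
            raise ValueError(f"unknown side_basis {self.side_basis!r}")


@dataclass
class Frame:
    """One configuration: a peptide model plus lipid pseudo-molecules.

    ``box`` (3,) in nm enables minimum-image distances; ``None`` means a
    non-periodic cluster.
    """

    peptide: object
    lipids: list
    box: np.ndarray = None


@dataclass
class ContactBreakdown:
    """Per-frame contact census.

    ``s_rot = w_dp*n_dp + w_dh*n_dh + w_ah*n_ah + w_ap*n_ap`` exactly, with
    the weights recorded alongside.  ``trp_head_contacts`` and the side
    census fields are filled by :func:`analyze_frame`.
    """

    n_dp: int = 0
    n_dh: int = 0
    n_ah: int = 0
    n_ap: int = 0
    s_rot: float = 0.0
    weights: tuple = (1.0, 1.0, -1.0, -1.0)
    trp_head_contacts: int | None = None
    n_des: int | None = None
    n_asc: int | None = None
    delta_n: int | None = None


@dataclass
class SwitchReport:
    """Debounced descending/ascending switching over a trajectory."""

    per_lipid: dict
    n_switching_lipids: int
    total_switches: int
    debounce: int


def _min_image(diff: np.ndarray, box) -> np.ndarray:
    if box is None:
        return diff
    box = np.asarray(box, dtype=float)
    out = diff.copy()
    for k in range(3):
        if box[k] > 0:
            out[..., k] -= box[k] * np.round(out[..., k] / box[k])
    return out


def _pair_dists(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    """(len(a), len(b)) distance matrix with optional minimum image."""
    diff = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(_min_image(diff, box), axis=-1)


def _lipid_atoms(lipid):
    head = np.atleast_2d(np.asarray(lipid.head_atoms, dtype=float))
    tail = np.atleast_2d(np.asarray(lipid.tail_atoms, dtype=float))
    if head.size == 0 or tail.size == 0:
        raise LipidPartitionError(
            f"lipid {getattr(lipid, 'lipid_id', '?')} lacks a head/tail partition")
    c2 = np.atleast_2d(np.asarray(lipid.c2_atom, dtype=float))
    coords = np.vstack([head, c2, tail])
    classes = np.array(["head"] * len(head) + ["c2"] * len(c2) + ["tail"] * len(tail))
    return coords, classes


def ambient_lipids(frame: Frame, policy: ContactPolicy) -> list:
    """Ids of lipids whose nearest heavy atom is within the ambient cutoff.

    The lipid-peptide distance is the minimum over all heavy-atom pairs.
    """
    pep = frame.peptide.heavy_coords()
    out = []
    for lipid in frame.lipids:
        coords, _ = _lipid_atoms(lipid)
        if _pair_dists(pep, coords, frame.box).min() <= policy.ambient_cutoff:
            out.append(lipid.lipid_id)
    return out


def frame_sides(frame: Frame, policy: ContactPolicy, helix=None,
                ambient: list | None = None) -> dict:
    """Descending/ascending label for each ambient lipid.

    Uses the peptide chirality's rotation sense and the lipid's C2 atom
    (or center of mass, per ``policy.side_basis``).  Returns
    ``{lipid_id: "des" | "asc"}``.
    """
    if helix is None:
        helix = geometry.helix_axis(frame.peptide.ca_coords())
    if ambient is None:
        ambient = ambient_lipids(frame, policy)
    lipids = [l for l in frame.lipids if l.lipid_id in set(ambient)]
    if not lipids:
        return {}
    if policy.side_basis == "c2":
        pts = np.array([np.asarray(l.c2_atom, dtype=float).reshape(3) for l in lipids])
    else:
        pts = np.array([_lipid_atoms(l)[0].mean(axis=0) for l in lipids])
    labels, _ = geometry.classify_sides(pts, helix, frame.peptide.chirality)
    return {l.lipid_id: lab for l, lab in zip(lipids, labels)}


def count_contacts(frame: Frame, sides: dict, policy: ContactPolicy) -> ContactBreakdown:
    """Classified residue-lipid contact counts and the S_rot score.

    A (residue, lipid) pair contributes one contact per heavy-atom pair
    within the contact cutoff.  Each contact is classified by the lipid's
    side label and by interaction type from the contacting lipid atom
    (head -> polar, tail -> hydrophobic; the C2 atom is assigned to the
    nearer of the two classes' atoms).  In ``strict`` mode only
    (nonpolar residue, tail atom) and (polar_charged residue, head atom)
    pairs are counted.
    """
    pep = frame.peptide
    counts = {"dp": 0, "dh": 0, "ap": 0, "ah": 0}
    lipids = {l.lipid_id: l for l in frame.lipids}
    for lid, side in sides.items():
        lipid = lipids[lid]
        coords, classes = _lipid_atoms(lipid)
        for res in pep.residue_indices():
            res_atoms = pep.residue_heavy_coords(res)
            d = _pair_dists(res_atoms, coords, frame.box)
            if d.min() > policy.contact_cutoff:
                continue
            # nearest lipid atom in the head/tail partition decides the type
            ht = classes != "c2"
            nearest = classes[ht][np.argmin(d[:, ht].min(axis=0))]
            atom_type = "p" if nearest == "head" else "h"
            res_type = "p" if pep.polarity_class[res] == "polar_charged" else "h"
            if policy.mixed_mode == "strict" and atom_type != res_type:
                continue
            key = ("d" if side == DESCENDING else "a") + atom_type
            counts[key] += 1
    w_dp, w_dh, w_ah, w_ap = policy.weights
    s_rot = (w_dp * counts["dp"] + w_dh * counts["dh"]
             + w_ah * counts["ah"] + w_ap * counts["ap"])
    return ContactBreakdown(n_dp=counts["dp"], n_dh=counts["dh"],
                            n_ah=counts["ah"], n_ap=counts["ap"],
                            s_rot=float(s_rot), weights=tuple(policy.weights))


def trp_head_contacts(frame: Frame, policy: ContactPolicy) -> int:
    """Number of distinct lipids with a head atom near the Trp residue.

    A lipid counts (once -- a Trp-lipid pair forms at most one contact) if
    any of its head-group atoms is within the contact cutoff of any heavy
    atom of the Trp residue.
    """
    pep = frame.peptide
    if pep.trp_index is None:
        raise geometry.GeometryError("peptide has no Trp residue")
    trp = pep.residue_heavy_coords(pep.trp_index)
    n = 0
    for lipid in frame.lipids:
        head = np.atleast_2d(np.asarray(lipid.head_atoms, dtype=float))
        if head.size == 0:
            raise LipidPartitionError(
                f"lipid {getattr(lipid, 'lipid_id', '?')} lacks head atoms")
        if _pair_dists(trp, head, frame.box).min() <= policy.contact_cutoff:
            n += 1
    return n


def side_census(sides: dict):
    """(n_des, n_asc, delta_n) over the ambient lipids' side labels."""
    n_des = sum(1 for s in sides.values() if s == DESCENDING)
    n_asc = sum(1 for s in sides.values() if s == ASCENDING)
    return n_des, n_asc, n_des - n_asc


def analyze_frame(frame: Frame, policy: ContactPolicy, helix=None) -> ContactBreakdown:
    """Full per-frame census: ambient filter, sides, contacts, Trp, delta_n."""
    if helix is None:
        helix = geometry.helix_axis(frame.peptide.ca_coords())
    ambient = ambient_lipids(frame, policy)
    sides = frame_sides(frame, policy, helix=helix, ambient=ambient)
    breakdown = count_contacts(frame, sides, policy)
    n_des, n_asc, delta = side_census(sides)
    return replace(breakdown,
                   trp_head_contacts=trp_head_contacts(frame, policy),
                   n_des=n_des, n_asc=n_asc, delta_n=delta)


def switch_events(label_series: dict, debounce: int = 5) -> SwitchReport:
    """Count debounced descending/ascending switches per lipid.

    ``label_series`` maps lipid id to its side-label sequence on a common
    frame clock (all sequences must have equal length).  A switch is a
    label change that persists for at least ``debounce`` consecutive
    frames; shorter excursions are flicker and do not count.
    """
    lengths = {len(v) for v in label_series.values()}
    if len(lengths) > 1:
        raise ValueError(f"mismatched frame counts between series: {sorted(lengths)}")
    per_lipid = {}
    for lid, seq in label_series.items():
        seq = list(seq)
        # run-length encode
        runs = []
        for lab in seq:
            if runs and runs[-1][0] == lab:
                runs[-1][1] += 1
            else:
                runs.append([lab, 1])
        count = 0
        accepted = runs[0][0] if runs else None
        for lab, length in runs[1:]:
            if lab != accepted and length >= debounce:
                accepted = lab
                count += 1
        per_lipid[lid] = count
    switching = sum(1 for c in per_lipid.values() if c >= 1)
    return SwitchReport(per_lipid=per_lipid, n_switching_lipids=switching,
                        total_switches=sum(per_lipid.values()), debounce=debounce)


def switch_difference(report_l: SwitchReport, report_d: SwitchReport) -> int:
    """delta_n_switch = n_switch(L) - n_switch(D), by switching-lipid count."""
    return report_l.n_switching_lipids - report_d.n_switching_lipids
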