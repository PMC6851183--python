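"""Independent brute-force oracles used by the test suite.

These re-derive, by the most literal computation available, the quantities
the package computes by faster or more structured routes.  They share the
rule definitions (an explicit ContactRuleSet) but none of the
implementation code paths.
"""

from __future__ import annotations

import math

import numpy as np

from ndpdesign.structure import (CTERM_OXYGENS, ContactRuleSet,
                                 StructureModel)


# ---------------------------------------------------------------------------
# Direct-sum Fourier transform
# ---------------------------------------------------------------------------

def direct_sum_amplitudes(values, pad_length: int,
                          mean_center: bool = True) -> np.ndarray:
    """O(N^2) discrete Fourier amplitude spectrum of a zero-padded series,
    bins k = 1..floor(pad/2), computed term by term."""
    x = list(values)
    if mean_center:
        mu = sum(x) / len(x)
        x = [v - mu for v in x]
    x = x + [0.0] * (pad_length - len(x))
    out = []
    for k in range(1, pad_length // 2 + 1):
        re = sum(x[n] * math.cos(2 * math.pi * k * n / pad_length)
                 for n in range(pad_length))
        im = -sum(x[n] * math.sin(2 * math.pi * k * n / pad_length)
                  for n in range(pad_length))
        out.append(math.hypot(re, im))
    return np.array(out)


def direct_sum_amplitude_at(values, F: float,
                            mean_center: bool = True) -> float:
    x = list(values)
    if mean_center:
        mu = sum(x) / len(x)
        x = [v - mu for v in x]
    re = sum(v * math.cos(2 * math.pi * F * n) for n, v in enumerate(x))
    im = -sum(v * math.sin(2 * math.pi * F * n) for n, v in enumerate(x))
    return math.hypot(re, im)


# ---------------------------------------------------------------------------
# Brute-force contact classification
# ---------------------------------------------------------------------------

def _dist(a, b) -> float:
    return float(np.linalg.norm(a.position - b.position))


def _angle(p1, p2, p3) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _is_positive(a, rules) -> bool:
    return a.atom_name in rules.positive_atoms.get(a.residue_name, ())


def _is_negative(a, rules) -> bool:
    return (a.atom_name in CTERM_OXYGENS
            or a.atom_name in rules.negative_atoms.get(a.residue_name, ()))


def _is_alkyl(a, rules) -> bool:
    return a.atom_name in rules.alkyl_atoms.get(a.residue_name, ())


def _is_donor_heavy(a, rules) -> bool:
    return (a.atom_name in rules.donor_heavy_atoms.get("*", ())
            or a.atom_name in rules.donor_heavy_atoms.get(a.residue_name, ()))


def _grouped(model: StructureModel, chain: str):
    groups: dict = {}
    for a in model.atoms:
        if a.chain == chain:
            groups.setdefault((a.chain, a.residue_number), []).append(a)
    return groups


def _h_parent(res_atoms, h):
    heavies = [a for a in res_atoms if a.element != "H"]
    best, best_d = None, None
    for a in heavies:
        d = _dist(a, h)
        if best_d is None or d < best_d:
            best, best_d = a, d
    if best is not None and best_d <= 1.3:
        return best
    return None


def _residue_sel(a) -> str:
    return f"{a.chain}:{a.residue_name}{a.residue_number}"


def _rings(groups, rules):
    out = []
    for atoms in groups.values():
        resname = atoms[0].residue_name
        for names in rules.ring_atoms.get(resname, ()):
            ring = [a for a in atoms if a.atom_name in names]
            if len(ring) != len(names):
                continue
            pts = np.array([a.position for a in ring])
            cen = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - cen)
            out.append((_residue_sel(ring[0]), cen, vt[2]))
    return out


def _amides(groups):
    out = []
    keys = list(groups)
    for i in range(len(keys) - 1):
        ra, rb = groups[keys[i]], groups[keys[i + 1]]
        c = [a for a in ra if a.atom_name == "C"]
        o = [a for a in ra if a.atom_name == "O"]
        n = [a for a in rb if a.atom_name == "N"]
        if not (c and o and n):
            continue
        c, o, n = c[0], o[0], n[0]
        if _dist(c, n) > 2.0:
            continue
        pts = np.array([c.position, o.position, n.position])
        cen = pts.mean(axis=0)
        nv = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        if np.linalg.norm(nv) == 0:
            continue
        nv = nv / np.linalg.norm(nv)
        sel = (f"{c.chain}:{c.residue_name}{c.residue_number}:C,O;"
               f"{n.residue_name}{n.residue_number}:N")
        out.append((sel, cen, nv))
    return out


def oracle_contacts(model: StructureModel, chain_a: str, chain_b: str,
                    rules: ContactRuleSet) -> set[tuple]:
    """Every contact record the rule set admits, as a set of comparable
    tuples (from, to, category, type, distance rounded to 6 decimals)."""
    ga, gb = _grouped(model, chain_a), _grouped(model, chain_b)
    has_h = any(a.element == "H" for a in model.atoms)
    found: set[tuple] = set()
    bridged: set[tuple] = set()

    def key(a):
        return (a.chain, a.residue_number, a.atom_name)

    # salt bridges
    if has_h:
        for gx, gy in ((ga, gb), (gb, ga)):
            for res in gx.values():
                for h in res:
                    if h.element != "H":
                        continue
                    p = _h_parent(res, h)
                    if p is None or not _is_positive(p, rules):
                        continue
                    for yres in gy.values():
                        for o in yres:
                            if o.element != "O" or not _is_negative(o, rules):
                                continue
                            d = _dist(h, o)
                            if d > rules.hbond_HA_max:
                                continue
                            ang = _angle(p.position, h.position, o.position)
                            if ang < rules.hbond_angle_min:
                                continue
                            bridged.add((key(p), key(o)))
                            found.add((h.selector, o.selector,
                                       "Hydrogen Bond; Electrostatic",
                                       "Salt Bridge; Attractive Charge",
                                       round(d, 6)))

    # attractive charge
    for gx, gy in ((ga, gb), (gb, ga)):
        for res in gx.values():
            for p in res:
                if p.element == "H" or not _is_positive(p, rules):
                    continue
                for yres in gy.values():
                    for n in yres:
                        if n.element == "H" or not _is_negative(n, rules):
                            continue
                        if (key(p), key(n)) in bridged:
                            continue
                        d = _dist(p, n)
                        if d <= rules.attractive_charge_max:
                            found.add((p.selector, n.selector,
                                       "Electrostatic", "Attractive Charge",
                                       round(d, 6)))

    # hydrogen bonds
    for gx, gy in ((ga, gb), (gb, ga)):
        for res in gx.values():
            if has_h:
                for h in res:
                    if h.element != "H":
                        continue
                    p = _h_parent(res, h)
                    if p is None:
                        continue
                    if p.element == "C":
                        cut, typ = rules.carbon_hbond_HA_max, \
                            "Carbon Hydrogen Bond"
                    elif p.element in ("N", "O", "S"):
                        cut, typ = rules.hbond_HA_max, \
                            "Conventional Hydrogen Bond"
                    else:
                        continue
                    for yres in gy.values():
                        for o in yres:
                            if o.element != "O":
                                continue
                            if _is_positive(p, rules) \
                                    and _is_negative(o, rules):
                                continue
                            d = _dist(h, o)
                            if d > cut:
                                continue
                            ang = _angle(p.position, h.position, o.position)
                            if ang >= rules.hbond_angle_min:
                                found.add((h.selector, o.selector,
                                           "Hydrogen Bond", typ,
                                           round(d, 6)))
            else:
                for p in res:
                    if p.element == "C":
                        cut, typ = rules.carbon_hbond_DA_max, \
                            "Carbon Hydrogen Bond"
                    elif p.element in ("N", "O", "S") \
                            and _is_donor_heavy(p, rules):
                        cut, typ = rules.hbond_DA_max, \
                            "Conventional Hydrogen Bond"
                    else:
                        continue
                    for yres in gy.values():
                        for o in yres:
                            if o.element != "O":
                                continue
                            if _is_positive(p, rules) \
                                    and _is_negative(o, rules):
                                continue
                            d = _dist(p, o)
                            if d <= cut:
                                found.add((p.selector, o.selector,
                                           "Hydrogen Bond", typ,
                                           round(d, 6)))

    # amide-pi
    for gx, gy in ((ga, gb), (gb, ga)):
        for asel, acen, anorm in _amides(gx):
            for rsel, rcen, rnorm in _rings(gy, rules):
                d = float(np.linalg.norm(acen - rcen))
                if d > rules.amide_pi_max:
                    continue
                cos = abs(float(np.dot(anorm, rnorm)))
                theta = math.degrees(math.acos(min(1.0, cos)))
                if theta <= rules.amide_pi_angle_max:
                    found.add((asel, rsel, "Hydrophobic",
                               "Amide-Pi Stacked", round(d, 6)))

    # pi-alkyl
    for gx, gy in ((ga, gb), (gb, ga)):
        for rsel, rcen, _n in _rings(gx, rules):
            for yres in gy.values():
                alk = [a for a in yres if _is_alkyl(a, rules)]
                if not alk:
                    continue
                d = min(float(np.linalg.norm(rcen - a.position))
                        for a in alk)
                if d <= rules.pi_max:
                    found.add((rsel, _residue_sel(alk[0]), "Hydrophobic",
                               "Pi-Alkyl", round(d, 6)))

    # alkyl
    for ares in ga.values():
        alk_a = [a for a in ares if _is_alkyl(a, rules)]
        if not alk_a:
            continue
        for bres in gb.values():
            alk_b = [b for b in bres if _is_alkyl(b, rules)]
            if not alk_b:
                continue
            d = min(_dist(a, b) for a in alk_a for b in alk_b)
            if d <= rules.hydrophobic_max:
                found.add((_residue_sel(alk_a[0]), _residue_sel(alk_b[0]),
                           "Hydrophobic", "Alkyl", round(d, 6)))

    return found


def contacts_as_set(records) -> set[tuple]:
    """Project implementation ContactRecords onto the oracle's tuple form."""
    return {(r.from_selector, r.to_selector, r.category, r.type,
             round(r.distance, 6)) for r in records}
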