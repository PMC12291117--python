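"""Deterministic gas-phase protonation-site assignment.

Native electrospray deposits a known net charge on an ion; to prepare a
gas-phase model at that charge the acidic sites must be protonated in a
reproducible order. The protocol implemented here:

(a) existing positive charges (Lys, Arg, His side chains, chain
    N-termini) are preserved and never deprotonated;
(b) solvent-accessible acidic sites not in salt bridges are protonated
    first, by descending pKa then descending SASA;
(c) accessible acidic sites in salt bridges follow, by ascending bridge
    distance, then descending pKa, then descending SASA;
(d) buried acidic sites come last (descending pKa, then site order).

The result is a plan - an ordered site list with a protonated prefix -
rather than modified coordinates; hydrogen placement is left to the
modelling package consuming the plan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core import Structure, sasa

logger = logging.getLogger(__name__)

DEFAULT_SB_CUTOFF = 4.0  # N-O heavy-atom distance, Angstrom
DEFAULT_BURIAL_THRESHOLD = 5.0  # group SASA below this => buried, A^2

BASIC_SIDECHAIN_ATOMS = {
    "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"],
    "HIS": ["ND1", "NE2"],
}
ACIDIC_SIDECHAIN_ATOMS = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
}


class InfeasibleChargeError(ValueError):
    """Target charge unreachable by protonating/keeping the available sites."""


def load_pka_table(path=None) -> dict[str, float]:
    """Site-kind -> intrinsic pKa; default bundled model values."""
    if path is None:
        text = resources.files("oligogrowth").joinpath("data/pka.csv").read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split(",")
        table[k.strip().upper()] = float(v)
    return table


def load_residue_defs(path=None) -> dict:
    """Titratable-group definitions for nonstandard residues (e.g. D6M)."""
    if path is None:
        text = resources.files("oligogrowth").joinpath("data/residue_defs.json").read_text()
    else:
        text = Path(path).read_text()
    return json.loads(text)


@dataclass
class TitratableSite:
    """A protonatable/charged group with its ordering keys."""

    site_id: str
    kind: str  # 'basic_fixed' or 'acidic'
    pka: float
    sasa: float = 0.0
    salt_bridge_distance: float | None = None
    buried: bool = False
    atom_indices: list[int] = field(default_factory=list)  # into structure.atoms
    order: int = 0  # enumeration order, final tie-break

    @property
    def charge(self) -> int:
        return +1 if self.kind == "basic_fixed" else -1


def enumerate_sites(
    structure: Structure,
    pka_table: dict[str, float] | None = None,
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    residue_defs: dict | None = None,
    precomputed_sasa: np.ndarray | None = None,
) -> list[TitratableSite]:
    """Find basic-fixed and acidic sites and fill their SASA ordering keys.

    Basic: Lys/Arg/His side chains and each chain's N-terminus. Acidic:
    Asp/Glu side chains, each chain's C-terminus, plus groups declared in
    ``residue_defs`` for nonstandard residues (D6M's glutamate carboxylate
    by default; its acylated amine is not basic). Residues missing their
    expected titratable atoms are skipped with a warning.
    """
    pka_table = pka_table or load_pka_table()
    residue_defs = residue_defs if residue_defs is not None else load_residue_defs()
    atoms = structure.atoms
    atom_pos = {id(a): i for i, a in enumerate(atoms)}
    if precomputed_sasa is None:
        per_atom, _ = sasa(structure)
    else:
        per_atom = precomputed_sasa

    sites: list[TitratableSite] = []

    def add(site_id, kind, pka_key, res_atoms, names):
        idx = [atom_pos[id(a)] for a in res_atoms if a.name in names]
        if not idx:
            logger.warning("site %s skipped: expected atoms %s not found", site_id, names)
            return
        g_sasa = float(per_atom[idx].sum())
        sites.append(
            TitratableSite(
                site_id=site_id,
                kind=kind,
                pka=pka_table[pka_key],
                sasa=g_sasa,
                buried=g_sasa < burial_threshold,
                atom_indices=idx,
                order=len(sites),
            )
        )

    for cid, residues in structure.chains.items():
        # termini
        first, last = residues[0], residues[-1]
        add(f"NTER:{cid}", "basic_fixed", "NTER", first.atoms, {"N"})
        cterm_names = {"OXT"} if any(a.name == "OXT" for a in last.atoms) else {"O"}
        add(f"CTER:{cid}", "acidic", "CTER", last.atoms, cterm_names)
        for res in residues:
            tag = f"{res.name}{res.index}:{cid}"
            if res.name in BASIC_SIDECHAIN_ATOMS:
                add(tag, "basic_fixed", res.name, res.atoms, set(BASIC_SIDECHAIN_ATOMS[res.name]))
            elif res.name in ACIDIC_SIDECHAIN_ATOMS:
                add(tag, "acidic", res.name, res.atoms, set(ACIDIC_SIDECHAIN_ATOMS[res.name]))
            elif res.name in residue_defs:
                spec = residue_defs[res.name]
                for g in spec.get("basic_groups", []):
                    add(f"{tag}:{g['tag']}", "basic_fixed", g["pka_key"], res.atoms, set(g["atoms"]))
                for g in spec.get("acidic_groups", []):
                    add(f"{tag}:{g['tag']}", "acidic", g["pka_key"], res.atoms, set(g["atoms"]))
    return sites


def titratable_sites_from_sequence(
    sequence: str,
    pka_table: dict[str, float] | None = None,
    chain_id: str = "A",
) -> list[TitratableSite]:
    """Sequence-only site enumeration (no structure, so no SASA/burial).

    ``sequence`` uses one-letter codes with 'X' for D6M (acylated lysine:
    not basic; contributes one acidic glutamate carboxylate). Useful for
    counting sites and sanity-checking charge feasibility.
    """
    pka_table = pka_table or load_pka_table()
    one2three = {"H": "HIS", "K": "LYS", "R": "ARG", "D": "ASP", "E": "GLU"}
    sites = [TitratableSite(f"NTER:{chain_id}", "basic_fixed", pka_table["NTER"])]
    seq = sequence.replace(" ", "").upper()
    for i, aa in enumerate(seq, start=1):
        if aa in ("K", "R", "H"):
            sites.append(TitratableSite(f"{one2three[aa]}{i}:{chain_id}", "basic_fixed", pka_table[one2three[aa]]))
        elif aa in ("D", "E"):
            sites.append(TitratableSite(f"{one2three[aa]}{i}:{chain_id}", "acidic", pka_table[one2three[aa]]))
        elif aa == "X":  # D6M: acylated amine, appended Glu carboxylate
            sites.append(TitratableSite(f"D6M{i}:{chain_id}:glu-carboxylate", "acidic", pka_table["GLU"]))
    sites.append(TitratableSite(f"CTER:{chain_id}", "acidic", pka_table["CTER"]))
    for k, s in enumerate(sites):
        s.order = k
    return sites


def detect_salt_bridges(
    structure: Structure,
    sites: list[TitratableSite],
    cutoff: float = DEFAULT_SB_CUTOFF,
) -> list[tuple[TitratableSite, TitratableSite, float]]:
    """Acid-base pairs whose closest O...N distance is within the cutoff.

    Each acidic site's ``salt_bridge_distance`` is set to its smallest
    such distance (None if unbridged). Returns the bridge list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = structure.atoms
    coords = structure.coords()
    bridges = []
    acids = [s for s in sites if s.kind == "acidic"]
    bases = [s for s in sites if s.kind == "basic_fixed"]
    for a in acids:
        a.salt_bridge_distance = None
        a_ox = [i for i in a.atom_indices if atoms[i].element == "O"]
        if not a_ox:
            continue
        best = None
        best_base = None
        for b in bases:
            b_n = [i for i in b.atom_indices if atoms[i].element == "N"]
            if not b_n:
                continue
            d = np.linalg.norm(coords[a_ox][:, None, :] - coords[b_n][None, :, :], axis=2).min()
            if best is None or d < best:
                best, best_base = float(d), b
        if best is not None and best <= cutoff:
            a.salt_bridge_distance = best
            bridges.append((a, best_base, best))
    return bridges


@dataclass
class ProtonationPlan:
    """Deterministic protonation order and the protonated prefix."""

    ordered_sites: list[TitratableSite]
    protonated: list[TitratableSite]
    initial_charge: int
    target_charge: int

    @property
    def final_charge(self) -> int:
        return self.initial_charge + len(self.protonated)

    def to_dict(self) -> dict:
        return {
            "initial_charge": self.initial_charge,
            "target_charge": self.target_charge,
            "final_charge": self.final_charge,
            "order": [s.site_id for s in self.ordered_sites],
            "protonated": [s.site_id for s in self.protonated],
        }


def protonation_order(sites: list[TitratableSite]) -> list[TitratableSite]:
    """The deterministic acidic-site protonation order (tiers b, c, d)."""
    acids = [s for s in sites if s.kind == "acidic"]
    tier_b = [s for s in acids if not s.buried and s.salt_bridge_distance is None]
    tier_c = [s for s in acids if not s.buried and s.salt_bridge_distance is not None]
    tier_d = [s for s in acids if s.buried]
    tier_b.sort(key=lambda s: (-s.pka, -s.sasa, s.order))
    tier_c.sort(key=lambda s: (s.salt_bridge_distance, -s.pka, -s.sasa, s.order))
    tier_d.sort(key=lambda s: (-s.pka, s.order))
    return tier_b + tier_c + tier_d


def plan_from_sites(sites: list[TitratableSite], target_charge: int) -> ProtonationPlan:
    """Build the plan from already-characterised sites (rules a-d)."""
    n_basic = sum(1 for s in sites if s.kind == "basic_fixed")
    n_acid = sum(1 for s in sites if s.kind == "acidic")
    initial = n_basic - n_acid
    need = target_charge - initial
    if need < 0:
        raise InfeasibleChargeError(
            f"target {target_charge} below initial charge {initial}: "
            "cannot remove protons from fixed positive sites"
        )
    if need > n_acid:
        raise InfeasibleChargeError(
            f"target {target_charge} needs {need} protons but only {n_acid} acidic sites exist"
        )
    order = protonation_order(sites)
    return ProtonationPlan(
        ordered_sites=order,
        protonated=order[:need],
        initial_charge=initial,
        target_charge=target_charge,
    )


def assign_protons(
    structure: Structure,
    target_charge: int,
    pka_table: dict[str, float] | None = None,
    sb_cutoff: float = DEFAULT_SB_CUTOFF,
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    residue_defs: dict | None = None,
) -> ProtonationPlan:
    """Enumerate sites, detect salt bridges, and plan protonation."""
    sites = enumerate_sites(
        structure, pka_table=pka_table, burial_threshold=burial_threshold, residue_defs=residue_defs
    )
    detect_salt_bridges(structure, sites, cutoff=sb_cutoff)
    return plan_from_sites(sites, target_charge)
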