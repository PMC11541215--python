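"""N-sequon occupancy scanning and the Asn amide-swap utility.

Scanning probes every Asn-X-Ser/Thr sequon with a single GlcNAc
monosaccharide using the full grafting protocol and reports a plain
yes/no per site: yes exactly when the probe can be placed with zero
steric loss.  Each sequon is probed against the bare protein — a
one-residue probe at another sequon should not change accessibility.

Crystallographic Asn sidechain amides are sometimes assigned with OD1 and
ND2 interchanged (electron density cannot tell N from O); the swap tool
exchanges the two coordinates so a blocked site can be re-probed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from glycokit.conformers.library import ConformerLibrary
from glycokit.core.linkage import LinkageSpec
from glycokit.core.model import MolecularModel
from glycokit.graft.attach import SiteRef, parse_site
from glycokit.graft.engine import GAConfig, GraftResult, graft_site

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class Sequon:
    """One Asn-X-Ser/Thr motif, in author numbering."""

    chain: str
    residue_number: int
    residue_name: str
    motif: str  # e.g. "NAS"
    insertion_code: str = ""
    kind: str = "N-linked"

    @property
    def site(self) -> SiteRef:
        return SiteRef(self.chain, self.residue_number, self.insertion_code)


@dataclass
class ScanReport:
    """Per-sequon occupancy labels with grafting diagnostics."""

    entries: list[tuple[Sequon, str, GraftResult | None]] = field(default_factory=list)
    protein_id: str = ""
    parameters: dict = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        return {str(s.site): label for s, label, _ in self.entries}

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "protein_id": self.protein_id,
            "parameters": self.parameters,
            "entries": [
                {
                    "site": str(s.site),
                    "motif": s.motif,
                    "label": label,
                    **({} if result is None else {
                        "cluster_used": None if result.pose is None
                        else result.pose.cluster_id,
                        "fitness_best": result.fitness,
                        "phase": result.phase,
                        "error": result.error,
                    }),
                }
                for s, label, result in self.entries
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def find_sequons(
    protein: MolecularModel, exclude_proline_x: bool = False
) -> list[Sequon]:
    """All N-X-S/T motifs per chain, in author order and numbering.

    A numbering gap (missing residues at a chain break) never creates a
    spurious motif; insertion-coded residues participate in authored
    order.  The literal NXS/T rule is applied by default; pass
    ``exclude_proline_x=True`` to reject X = Pro (the biologically
    conventional refinement).
    """
    residues = [r for r in protein.residues() if r[3] in _THREE_TO_ONE]
    sequons: list[Sequon] = []
    for first, second, third in zip(residues, residues[1:], residues[2:]):
        if not (_consecutive(first, second) and _consecutive(second, third)):
            continue
        if first[3] != "ASN":
            continue
        if third[3] not in ("SER", "THR"):
            continue
        if exclude_proline_x and second[3] == "PRO":
            continue
        motif = "".join(_THREE_TO_ONE[r[3]] for r in (first, second, third))
        sequons.append(
            Sequon(
                chain=first[0],
                residue_number=first[1],
                insertion_code=first[2],
                residue_name=first[3],
                motif=motif,
            )
        )
    return sequons


def _consecutive(r1: tuple, r2: tuple) -> bool:
    chain1, num1, icode1, _ = r1
    chain2, num2, icode2, _ = r2
    if chain1 != chain2:
        return False
    if icode1 or icode2:  # insertion-coded: authored adjacency governs
        return num2 - num1 in (0, 1)
    return num2 - num1 == 1


def glcnac_scan(
    protein: MolecularModel,
    library: ConformerLibrary,
    linkage: LinkageSpec,
    config: GAConfig | None = None,
    exclude_proline_x: bool = False,
    protein_id: str = "",
) -> ScanReport:
    """Probe every sequon with a single GlcNAc; label yes iff clash-free.

    A sequon whose Asn lacks the ND2 attachment atom is labelled no with
    reason ``sidechain-atom-missing`` and a pointer to the swap tool.
    """
    config = config or GAConfig()
    report = ScanReport(
        protein_id=protein_id,
        parameters={
            "population_size": config.population_size,
            "generations": config.generations,
            "mutation_rate": config.mutation_rate,
            "seed": config.seed,
            "exclude_proline_x": exclude_proline_x,
        },
    )
    for sequon in find_sequons(protein, exclude_proline_x=exclude_proline_x):
        result = graft_site(protein, sequon.site, library, linkage, config=config)
        label = "yes" if result.success else "no"
        report.entries.append((sequon, label, result))
    return report


def swap_asn_amide(protein: MolecularModel, site: SiteRef | str) -> MolecularModel:
    """Exchange the OD1 and ND2 coordinates of an Asn sidechain.

    Returns a new model; applying the swap twice restores the original.
    """
    site = parse_site(site)
    model = protein.copy()
    res_atoms = model.residue_atoms(site.chain, site.residue_number,
                                    site.insertion_code)
    if not res_atoms:
        raise ValueError(f"site {site}: no residue found")
    if model.atoms[res_atoms[0]].residue_name != "ASN":
        raise ValueError(
            f"site {site} is {model.atoms[res_atoms[0]].residue_name}, not ASN"
        )
    od1 = [i for i in res_atoms if model.atoms[i].name == "OD1"]
    nd2 = [i for i in res_atoms if model.atoms[i].name == "ND2"]
    if not (od1 and nd2):
        raise ValueError(f"site {site}: needs both OD1 and ND2 to swap")
    a, b = od1[0], nd2[0]
    a_xyz = model.atoms[a].coordinates.copy()
    model.atoms[a].coordinates = model.atoms[b].coordinates.copy()
    model.atoms[b].coordinates = a_xyz
    return model
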