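"""Merging uncorrelated trajectory replicas into one heavy-atom ensemble.

Hydrogens carry no conformational information at this resolution and are
stripped at the merge step; frames are stacked in replica order and each
frame remembers which replica produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from glycokit.core.model import MolecularModel


@dataclass
class ConformationEnsemble:
    """Aligned-atom heavy-atom coordinate stack over F frames.

    ``template`` is a MolecularModel with the ensemble's atom composition,
    used to materialize any frame back into a writable structure.
    """

    frames: np.ndarray  # (F, N, 3), Å
    template: MolecularModel
    replica_of: np.ndarray = field(default=None)  # replica index per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.replica_of is None:
            self.replica_of = np.zeros(len(self.frames), dtype=int)
        self.replica_of = np.asarray(self.replica_of, dtype=int)
        if len(self.replica_of) != len(self.frames):
            raise ValueError("replica_of length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def atom_meta(self) -> list[tuple[str, str, str]]:
        return [(a.name, a.element, a.residue_name) for a in self.template.atoms]

    def frame_model(self, index: int) -> MolecularModel:
        """Materialize frame ``index`` as a structure."""
        model = self.template.copy()
        model.set_coordinates(self.frames[index])
        model.model_id = index + 1
        return model

    @classmethod
    def from_models(
        cls, models: list[MolecularModel], replica: int = 0
    ) -> "ConformationEnsemble":
        """Build a (single-replica) ensemble from parsed multi-model frames."""
        if not models:
            raise ValueError("no frames supplied")
        stripped = [m.strip_hydrogens() for m in models]
        template = stripped[0]
        keys = [a.key for a in template.atoms]
        frames = np.empty((len(stripped), len(keys), 3))
        frames[0] = template.coordinates
        for f, m in enumerate(stripped[1:], start=1):
            frames[f] = _matched_coordinates(m, keys, frame=f)
        return cls(
            frames=frames,
            template=template,
            replica_of=np.full(len(stripped), replica, dtype=int),
        )


def _matched_coordinates(
    model: MolecularModel, keys: list[tuple], frame: int
) -> np.ndarray:
    """Coordinates of ``model`` reordered to the reference atom keys."""
    lookup = {a.key: a.coordinates for a in model.atoms}
    if len(lookup) != len(model.atoms):
        raise ValueError(f"frame {frame}: duplicate atom identities")
    coords = np.empty((len(keys), 3))
    for i, key in enumerate(keys):
        try:
            coords[i] = lookup.pop(key)
        except KeyError:
            raise ValueError(
                f"atom-composition mismatch at frame {frame}: reference atom "
                f"{key} missing"
            ) from None
    if lookup:
        extra = next(iter(lookup))
        raise ValueError(
            f"atom-composition mismatch at frame {frame}: unexpected atom {extra}"
        )
    return coords


def merge_replicas(
    trajectories: list["ConformationEnsemble | list[MolecularModel]"],
) -> ConformationEnsemble:
    """Concatenate replicas into one ensemble (hydrogens stripped).

    Replicas must share the same heavy-atom composition; atoms permuted
    between replicas are re-matched by identity to the first replica's
    ordering, so downstream pairwise distances are unaffected.
    """
    if not trajectories:
        raise ValueError("no replicas supplied")
    ensembles: list[ConformationEnsemble] = []
    for r, traj in enumerate(trajectories):
        if isinstance(traj, ConformationEnsemble):
            ens = ConformationEnsemble(
                frames=traj.frames.copy(),
                template=traj.template.copy(),
                replica_of=np.full(traj.n_frames, r, dtype=int),
            )
        else:
            ens = ConformationEnsemble.from_models(traj, replica=r)
        ensembles.append(ens)
    reference = ensembles[0]
    ref_keys = [a.key for a in reference.template.atoms]
    stacks = [reference.frames]
    replica_of = [reference.replica_of]
    for ens in ensembles[1:]:
        keys = [a.key for a in ens.template.atoms]
        if keys == ref_keys:
            stacks.append(ens.frames)
        else:
            order = _match_order(ref_keys, keys)
            stacks.append(ens.frames[:, order, :])
        replica_of.append(ens.replica_of)
    return ConformationEnsemble(
        frames=np.concatenate(stacks, axis=0),
        template=reference.template.copy(),
        replica_of=np.concatenate(replica_of),
    )


def _match_order(ref_keys: list[tuple], keys: list[tuple]) -> list[int]:
    index = {key: i for i, key in enumerate(keys)}
    if len(index) != len(keys):
        raise ValueError("replica contains duplicate atom identities")
    order = []
    for key in ref_keys:
        if key not in index:
            raise ValueError(
                f"atom-composition mismatch between replicas: atom {key} "
                "absent from a later replica"
            )
        order.append(index[key])
    if len(keys) != len(ref_keys):
        extra = sorted(set(keys) - set(ref_keys))[0]
        raise ValueError(
            f"atom-composition mismatch between replicas: unexpected atom {extra}"
        )
    return order
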