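"""Block design of the sliding-to-target experiment.

A session comprises 12 blocks of (by default) 10 trials: the first six
blocks use one target distance, the last six the other, with three surface
slopes nested inside each of two surface materials.  Four counterbalancing
groups exist: groups 1–2 run the slopes in the order (0°, −10°, +10°)
within each material, groups 3–4 in the order (0°, +10°, −10°); odd groups
start with aluminum, even groups with balsa wood.
"""

from __future__ import annotations

from dataclasses import dataclass

ALUMINUM = "aluminum"
BALSA = "balsa"

#: Slope order within each three-block material triplet, per group.
SLOPE_ORDERS = {
    1: (0.0, -10.0, 10.0),
    2: (0.0, -10.0, 10.0),
    3: (0.0, 10.0, -10.0),
    4: (0.0, 10.0, -10.0),
}

#: Material of the four successive triplets (blocks 1–3, 4–6, 7–9, 10–12).
MATERIAL_ORDERS = {
    1: (ALUMINUM, BALSA, ALUMINUM, BALSA),
    2: (BALSA, ALUMINUM, BALSA, ALUMINUM),
    3: (ALUMINUM, BALSA, ALUMINUM, BALSA),
    4: (BALSA, ALUMINUM, BALSA, ALUMINUM),
}

#: Target distance (m) for the two session halves (blocks 1–6, 7–12).
TARGET_DISTANCES = (0.25, 0.50)


@dataclass(frozen=True)
class Block:
    number: int  # 1-based
    target_distance: float  # m
    slope: float  # degrees
    material: str


@dataclass(frozen=True)
class ExperimentDesign:
    group_id: int
    blocks: tuple[Block, ...]
    trials_per_block: int = 10

    @property
    def n_trials(self) -> int:
        return len(self.blocks) * self.trials_per_block

    def iter_trials(self):
        """Yield (block, trial_in_block 1-based, global trial 1-based)."""
        t = 0
        for block in self.blocks:
            for i in range(1, self.trials_per_block + 1):
                t += 1
                yield block, i, t


def make_design(group_id: int, trials_per_block: int = 10) -> ExperimentDesign:
    """Build the 12-block design for one counterbalancing group.

    Raises ``ValueError`` for group ids outside 1–4 or nonpositive trial
    counts.
    """
    if group_id not in SLOPE_ORDERS:
        raise ValueError(f"group_id must be in {{1, 2, 3, 4}}, got {group_id}")
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    slopes = SLOPE_ORDERS[group_id]
    materials = MATERIAL_ORDERS[group_id]
    blocks = []
    n = 0
    for half, distance in enumerate(TARGET_DISTANCES):
        for triplet in range(2):
            material = materials[2 * half + triplet]
            for slope in slopes:
                n += 1
                blocks.append(Block(n, distance, slope, material))
    return ExperimentDesign(group_id=group_id, blocks=tuple(blocks),
                            trials_per_block=trials_per_block)
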