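"""The 44-joint atlas underlying DAS44-style joint counts.

The atlas covers 22 bilateral joint sites (sternoclavicular through MTP5),
tags each joint with an anatomical region (hand / foot / large / other) and
marks the 28-joint DAS subset (shoulders, elbows, wrists, MCPs, PIPs, knees).
"""

from __future__ import annotations

from dataclasses import dataclass

# site name -> (region, das28 member); order defines the canonical joint order
_SITES: list[tuple[str, str, bool]] = [
    ("SC", "other", False),         # sternoclavicular
    ("AC", "other", False),         # acromioclavicular
    ("shoulder", "large", True),
    ("elbow", "large", True),
    ("wrist", "hand", True),
    *[(f"MCP{i}", "hand", True) for i in range(1, 6)],
    *[(f"PIP{i}", "hand", True) for i in range(1, 6)],
    ("knee", "large", True),
    ("ankle", "foot", False),
    *[(f"MTP{i}", "foot", False) for i in range(1, 6)],
]

SIDES = ("L", "R")


@dataclass(frozen=True)
class Joint:
    """A single joint: side 'L'/'R' (or 'M' for midline), anatomical site,
    region tag and DAS28 membership."""

    side: str
    name: str
    region: str
    das28_member: bool

    @property
    def joint_id(self) -> str:
        return f"{self.side}_{self.name}"


@dataclass(frozen=True)
class JointAtlas:
    """An ordered collection of joints defining the coordinate system for
    tender/swollen indicator vectors."""

    joints: tuple[Joint, ...]

    def __post_init__(self):
        ids = [j.joint_id for j in self.joints]
        if len(set(ids)) != len(ids):
            raise ValueError("joint identifiers must be unique")
        # left/right pairing must be total for non-midline joints
        sided = {(j.side, j.name) for j in self.joints if j.side != "M"}
        for side, name in sided:
            other = "R" if side == "L" else "L"
            if (other, name) not in sided:
                raise ValueError(f"unpaired joint {side}_{name}")

    def __len__(self) -> int:
        return len(self.joints)

    def __iter__(self):
        return iter(self.joints)

    @property
    def joint_ids(self) -> list[str]:
        return [j.joint_id for j in self.joints]

    def region(self, region: str) -> list[Joint]:
        return [j for j in self.joints if j.region == region]

    @property
    def das28_ids(self) -> list[str]:
        return [j.joint_id for j in self.joints if j.das28_member]

    def pairs(self) -> list[tuple[str, str]]:
        """Left/right joint-id pairs, in site order."""
        return [(f"L_{name}", f"R_{name}") for name, _, _ in _SITES
                if ("L", name) in {(j.side, j.name) for j in self.joints}]


def default_atlas() -> JointAtlas:
    """The default 44-joint atlas (22 bilateral sites).

    28 joints carry das28_member; the hand region has 22 joints
    (wrists, MCP1-5, PIP1-5 bilaterally) and the foot region 12
    (ankles, MTP1-5 bilaterally).
    """
    joints = tuple(
        Joint(side=side, name=name, region=region, das28_member=das28)
        for side in SIDES
        for name, region, das28 in _SITES
    )
    return JointAtlas(joints=joints)
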