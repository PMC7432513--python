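"""Canonical joint vocabulary for 25-joint body-tracking skeletons.

The Kinect V2 body-tracking SDK reports 25 named joints per skeleton.  For
seated subjects the fine hand joints (hand, hand tip, thumb) and the foot are
poorly tracked, so analysis restricts to a 17-joint subset; the wrist stands
in for the hand region and the ankle for the foot region.
"""

from __future__ import annotations

# Device enumeration order of the 25 joints.
CANONICAL_JOINTS: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "left_hand",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "right_hand",
    "left_hip",
    "left_knee",
    "left_ankle",
    "left_foot",
    "right_hip",
    "right_knee",
    "right_ankle",
    "right_foot",
    "spine_shoulder",
    "left_hand_tip",
    "left_thumb",
    "right_hand_tip",
    "right_thumb",
)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_JOINTS)}

# Joints rejected for seated recordings: hand region (hand, hand tip, thumb)
# on both sides, plus both feet.
REJECTED_JOINTS: frozenset[str] = frozenset(
    {
        "left_hand",
        "right_hand",
        "left_hand_tip",
        "right_hand_tip",
        "left_thumb",
        "right_thumb",
        "left_foot",
        "right_foot",
    }
)

# The 17 analysed joints, in canonical report order (trunk top-down, left arm,
# right arm, left leg, right leg, spine shoulder last).
ANALYSIS_JOINTS: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_hip",
    "right_knee",
    "right_ankle",
    "spine_shoulder",
)

assert len(ANALYSIS_JOINTS) == 17
assert set(ANALYSIS_JOINTS) == set(CANONICAL_JOINTS) - REJECTED_JOINTS

# Kinect SDK JointType spellings -> canonical tokens.
_SDK_ALIASES: dict[str, str] = {
    "SpineBase": "spine_base",
    "SpineMid": "spine_mid",
    "Neck": "neck",
    "Head": "head",
    "ShoulderLeft": "left_shoulder",
    "ElbowLeft": "left_elbow",
    "WristLeft": "left_wrist",
    "HandLeft": "left_hand",
    "ShoulderRight": "right_shoulder",
    "ElbowRight": "right_elbow",
    "WristRight": "right_wrist",
    "HandRight": "right_hand",
    "HipLeft": "left_hip",
    "KneeLeft": "left_knee",
    "AnkleLeft": "left_ankle",
    "FootLeft": "left_foot",
    "HipRight": "right_hip",
    "KneeRight": "right_knee",
    "AnkleRight": "right_ankle",
    "FootRight": "right_foot",
    "SpineShoulder": "spine_shoulder",
    "HandTipLeft": "left_hand_tip",
    "ThumbLeft": "left_thumb",
    "HandTipRight": "right_hand_tip",
    "ThumbRight": "right_thumb",
}

JOINT_ALIASES: dict[str, str] = {name: name for name in CANONICAL_JOINTS}
JOINT_ALIASES.update(_SDK_ALIASES)
# Space-separated spellings ("spine base", "left hand tip") are also accepted.
JOINT_ALIASES.update({name.replace("_", " "): name for name in CANONICAL_JOINTS})


def normalize_joint(name: str) -> str:
    """Map a joint spelling (canonical, SDK or space-separated) to its
    canonical token.

    Raises
    ------
    KeyError
        If the name is not one of the recognised spellings of the 25 joints.
    """
    try:
        return JOINT_ALIASES[name.strip()]
    except KeyError:
        raise KeyError(f"unknown joint name: {name!r}") from None
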