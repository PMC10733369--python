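"""Fixed vocabulary of the 28 joints queried by the DAS28 examination.

The 28-joint count covers shoulders, elbows, wrists, metacarpophalangeal
joints 1-5 (MCP), proximal interphalangeal joints 1-5 (PIP) and knees,
bilaterally.  Joint names are ``<joint><digit>_<side>`` (e.g. ``mcp2_right``
is the metacarpophalangeal joint of the right index finger).  The ordering
defined here is the canonical feature order used everywhere in the package;
CSV columns, 58-item feature vectors and importance tables all follow it.
"""

from __future__ import annotations

_BASES = (
    "shoulder",
    "elbow",
    "wrist",
    "mcp1",
    "mcp2",
    "mcp3",
    "mcp4",
    "mcp5",
    "pip1",
    "pip2",
    "pip3",
    "pip4",
    "pip5",
    "knee",
)

SIDES = ("left", "right")

#: Canonical order of the 28 joints.
JOINT_NAMES: tuple[str, ...] = tuple(f"{b}_{s}" for b in _BASES for s in SIDES)

#: CSV / feature names of the tender-joint flags, in canonical order.
TENDER_COLUMNS: tuple[str, ...] = tuple(f"tender_{j}" for j in JOINT_NAMES)

#: CSV / feature names of the swollen-joint flags, in canonical order.
SWOLLEN_COLUMNS: tuple[str, ...] = tuple(f"swollen_{j}" for j in JOINT_NAMES)

CRP_COLUMN = "crp_mg_l"
GH_COLUMN = "gh_mm"

#: The d = 58 item-level feature order: 28 tender flags, 28 swollen flags,
#: CRP concentration, patient global health.
FEATURE_NAMES_58: tuple[str, ...] = TENDER_COLUMNS + SWOLLEN_COLUMNS + (CRP_COLUMN, GH_COLUMN)

#: The d = 4 composite components, in canonical order.
COMPONENT_NAMES: tuple[str, ...] = ("tjc28", "sjc28", "crp", "gh")

#: The joint whose tenderness the cohort generator enriches in active disease
#: (base joint of the right index finger).
DEFAULT_SIGNAL_JOINT = "mcp2_right"

assert len(JOINT_NAMES) == 28
assert len(FEATURE_NAMES_58) == 58
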