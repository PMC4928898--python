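"""Measurement-quality class taxonomies.

Seven full-resolution classes: error-free plus the six artifact types.
Type-A is the classic hook effect (parasitic capacitive leakage bending
the high-frequency end of the arc); Type-B/C are capacitive outer tails
noticeable from the VHF band (B) or already from HF (C); Type-D is a
resistance-trend reversal producing an inner tail with still-negative
reactance; Type-E/F cross the resistance axis (reactance turns positive
at the top frequencies), without (E) or with (F) the resistance reversal.

The divide-and-conquer scheme first classifies five merged classes
(B+C and E+F pooled) and then splits the pooled pairs with one-feature
threshold classifiers.
"""

from __future__ import annotations

import enum

__all__ = ["ErrorClass", "MergedClass", "merge_label", "MERGED_OF"]


class ErrorClass(enum.IntEnum):
    """Full 7-class taxonomy (all-at-once scheme), classes 1..7."""

    CLEAN = 1
    TYPE_A = 2
    TYPE_B = 3
    TYPE_C = 4
    TYPE_D = 5
    TYPE_E = 6
    TYPE_F = 7


class MergedClass(enum.IntEnum):
    """5-class taxonomy for step 1 of the divide-and-conquer scheme."""

    CLEAN = 1
    TYPE_A = 2
    TYPE_BC = 3
    TYPE_D = 4
    TYPE_EF = 5


MERGED_OF: dict[ErrorClass, MergedClass] = {
    ErrorClass.CLEAN: MergedClass.CLEAN,
    ErrorClass.TYPE_A: MergedClass.TYPE_A,
    ErrorClass.TYPE_B: MergedClass.TYPE_BC,
    ErrorClass.TYPE_C: MergedClass.TYPE_BC,
    ErrorClass.TYPE_D: MergedClass.TYPE_D,
    ErrorClass.TYPE_E: MergedClass.TYPE_EF,
    ErrorClass.TYPE_F: MergedClass.TYPE_EF,
}


def merge_label(label: ErrorClass | int) -> MergedClass:
    """Map a full-resolution class to its merged (step-1) class."""
    return MERGED_OF[ErrorClass(label)]
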