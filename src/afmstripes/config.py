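"""Shared defaults and constants.

These values are shared between the phantom generator and the analysis
modules so that ground-truth labels and measured criteria cannot drift
apart (e.g. the straightness threshold that separates straight-linker
from bent-linker morphologies is used both when scripting phantoms and
when classifying measured molecules).
"""

#: Lateral calibration of the low-magnification AFM frames (nm per pixel).
DEFAULT_PIXEL_SIZE_NM = 1.5

#: Default frame size of low-magnification AFM images (rows, cols).
DEFAULT_FRAME_SHAPE = (240, 240)

#: Straightness threshold (degrees): a two-knot molecule whose linker bends
#: less than this is "straight" (class 1), otherwise "bent" (class 2).
STRAIGHTNESS_THRESHOLD_DEG = 30.0

#: Minimum peak height (nm) for a compact feature to count as knot-like:
#: the strand-like portion stays at or below ~3.5 nm, so anything rising
#: above that ceiling near a backbone end marks a knot or globule.
KNOT_MIN_HEIGHT_NM = 3.5

#: Prominence (nm) a local maximum of a backbone height profile must have
#: to be reported (half the strand/globule height gap).
PROFILE_PROMINENCE_NM = 0.5

#: Bead-assay defaults: microbead diameter and camera calibration.
BEAD_DIAMETER_UM = 1.6
BEAD_PIXEL_SIZE_UM = 0.943

#: Default five size-range edges for aggregate binning, in bead-area
#: multiples of the ~2 µm² single-bead footprint (the published inset does
#: not print its boundaries, so these are explicit, documented defaults).
DEFAULT_BIN_EDGES_UM2 = (2.0, 50.0, 200.0, 800.0, 3200.0)
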