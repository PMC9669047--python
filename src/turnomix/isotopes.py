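"""Pinned natural isotope abundances used for isotopologue correction.

Each element maps mass shift (in integer mass units above the monoisotopic
peak) to its natural frequency.  Values are the standard terrestrial
abundances; they are pinned here so corrected MIDs are bit-reproducible
across versions of any upstream source.
"""

from __future__ import annotations

# mass shift -> frequency; frequencies sum to 1 per element
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "Si": {0: 0.922297, 1: 0.046832, 2: 0.030872},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
}

TRACER_ELEMENT = "C"
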