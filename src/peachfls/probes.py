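"""Junction-probe construction for insertion presence/absence typing.

For each insertion site a pair of diagnostic sequences is built, both
starting with the same ``flank_len`` bases of upstream reference ending at
the insertion point:

* the *presence* probe continues into the inserted sequence (and, if the
  insert is shorter than the remaining window, onward into downstream
  reference), spanning the insertion junction;
* the *absence* probe continues directly into downstream reference,
  spanning the uninterrupted reference junction.

A read containing one of these probes as an exact full-length substring
diagnoses the corresponding allele state at the site.

Two modes are provided.  ``fixed_window`` (default) makes both probes
exactly ``window`` bases, giving symmetric match sensitivity.
``published_compat`` truncates the absence probe by the insert length whenever
the insert fits inside the window, reproducing byte-exactly the published
51-base exon-junction reference probe alongside 60-base presence probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .locus import (
    BoundsError,
    ConfigurationError,
    InsertionSite,
    ReferenceLocus,
    check_dna,
)

FIXED_WINDOW = "fixed_window"
PUBLISHED_COMPAT = "published_compat"
MODES = (FIXED_WINDOW, PUBLISHED_COMPAT)

DEFAULT_WINDOW = 60
DEFAULT_FLANK = 30


@dataclass(frozen=True)
class ProbePair:
    site_id: str
    presence_probe: str
    absence_probe: str
    flank_len: int
    window: int
    mode: str

    def __post_init__(self) -> None:
        if self.presence_probe[: self.flank_len] != self.absence_probe[: self.flank_len]:
            raise ConfigurationError(
                f"site {self.site_id!r}: probes do not share the upstream flank"
            )


def design_probes(
    locus: ReferenceLocus,
    site: InsertionSite,
    flank_len: int = DEFAULT_FLANK,
    window: int = DEFAULT_WINDOW,
    mode: str = FIXED_WINDOW,
) -> ProbePair:
    """Build the presence/absence probe pair for one insertion site."""
    if mode not in MODES:
        raise ConfigurationError(f"unknown probe mode {mode!r}; expected one of {MODES}")
    if flank_len < 1:
        raise ConfigurationError(f"flank_len must be >= 1, got {flank_len}")
    if window <= flank_len:
        raise ConfigurationError(
            f"window ({window}) must exceed flank_len ({flank_len})"
        )
    pos = site.position
    down = window - flank_len
    if pos < flank_len:
        raise BoundsError(
            f"site {site.site_id!r}: position {pos} leaves fewer than "
            f"{flank_len} upstream bases"
        )
    if pos + down > len(locus):
        raise BoundsError(
            f"site {site.site_id!r}: window of {window} exceeds locus end "
            f"({pos} + {down} > {len(locus)})"
        )
    ref = locus.sequence
    flank = ref[pos - flank_len : pos]
    presence = (flank + site.insert_seq + ref[pos:])[:window]

    if mode == PUBLISHED_COMPAT and len(site.insert_seq) < down:
        absence_down = down - len(site.insert_seq)
    else:
        absence_down = down
    absence = flank + ref[pos : pos + absence_down]

    for name, probe in (("presence", presence), ("absence", absence)):
        check_dna(probe, f"site {site.site_id!r} {name} probe")
    return ProbePair(
        site_id=site.site_id,
        presence_probe=presence,
        absence_probe=absence,
        flank_len=flank_len,
        window=window,
        mode=mode,
    )


def design_probe_set(
    locus: ReferenceLocus,
    sites: Iterable[InsertionSite],
    flank_len: int | Mapping[str, int] = DEFAULT_FLANK,
    window: int = DEFAULT_WINDOW,
    mode: str = FIXED_WINDOW,
) -> dict[str, ProbePair]:
    """Probe pairs for every site; ``flank_len`` may be per-site mapping."""
    out: dict[str, ProbePair] = {}
    for site in sites:
        f = flank_len[site.site_id] if isinstance(flank_len, Mapping) else flank_len
        out[site.site_id] = design_probes(locus, site, f, window, mode)
    return out
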