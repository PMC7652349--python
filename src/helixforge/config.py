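"""Tunable parameters, with defaults, for alignment and hybridization.

All thresholds the knowledge-based rules depend on live here so they can be
overridden from the CLI (``--config params.yaml``) or programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


#: Fallback sequence motifs used to anchor a transmembrane helix when the
#: x.50 anchor residue is not annotated. Each entry maps helix index ->
#: (pattern, offset of the anchor residue within the pattern). 'x' is a
#: wildcard. DRY sits at 3.49-3.51 (anchor = R), CWxP at 6.47-6.50
#: (anchor = P), NPxxY at 7.49-7.53 (anchor = P = 7.50).
DEFAULT_TM_MOTIFS: dict[int, tuple[str, int]] = {
    3: ("DRY", 1),
    6: ("CWxP", 3),
    7: ("NPxxY", 1),
}

#: Loop anchoring motifs: region name -> pattern (x = wildcard).
DEFAULT_LOOP_MOTIFS: dict[str, str] = {
    "ECL1": "xWxxG",
}


@dataclass
class AlignConfig:
    """Thresholds for the blended sequence/structure alignment.

    d_max : float
        CA deviation (A) from the column consensus that triggers an
        insertion/deletion while extending a helix alignment outward from
        its anchor. Chosen to separate a one-residue helix register slip
        (>= 3.8 A spatial displacement) from coordinate noise.
    d_loop : float
        Maximum CA-CA distance (A) for two loop residues to share a column.
    theta_max : float
        Maximum angle (degrees) between CA->CB unit vectors for two loop
        residues to share a column.
    termini_pad : int
        Number of terminal residues adjacent to TM1/TM7 retained in the
        identity mask; everything further out counts as "long termini" and
        is excluded from pairwise identity.
    """

    d_max: float = 2.0
    d_loop: float = 3.0
    theta_max: float = 60.0
    termini_pad: int = 10
    tm_motifs: dict = field(default_factory=lambda: dict(DEFAULT_TM_MOTIFS))
    loop_motifs: dict = field(default_factory=lambda: dict(DEFAULT_LOOP_MOTIFS))
    #: identity denominator: "shared" = mutually non-gap masked columns
    #: (the common percent-identity convention); "mask" = all masked columns.
    identity_denominator: str = "shared"


@dataclass
class ScoreWeights:
    """Weights of the lightweight composite hybridization score.

    clash/chainbreak/disulfide/rg are sums over the whole chain
    (extensive), while ss_agreement and template_consensus are
    per-residue averages (intensive). The consensus weight is therefore
    set near 0.25x a typical receptor length (~200 residues) so that
    drifting the model away from the superposed-template median costs as
    much as the residual strain it could relieve; with a weight of order
    1 the search slowly random-walks away from the templates while
    polishing virtual bonds.
    """

    clash: float = 1.0
    chainbreak: float = 10.0
    ss_agreement: float = 5.0
    disulfide: float = 10.0
    rg: float = 0.1
    template_consensus: float = 50.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class HybridConfig:
    """Monte Carlo schedule for :func:`helixforge.hybridize_lite.hybridize`."""

    n_models: int = 100
    n_steps: int = 5000
    t_start: float = 2.0
    t_end: float = 0.25
    swap_min: int = 5
    swap_max: int = 30
    flank: int = 3
    weights: ScoreWeights = field(default_factory=ScoreWeights)


def load_config(path) -> AlignConfig:
    """Load an :class:`AlignConfig` from a YAML file of overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = AlignConfig()
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key: {key}")
        setattr(cfg, key, value)
    return cfg
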