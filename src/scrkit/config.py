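"""Central run configuration.

Every numeric threshold used by the pipeline is declared exactly once here;
analysis stages take their defaults from :class:`RunConfig` rather than
hard-coding them. Runs are expected to emit the fully resolved configuration
alongside their results so every call is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .errors import ConfigError

#: Illumina TruSeq small-RNA 3' adapter prefix, the common ribo-seq adapter.
DEFAULT_ADAPTER3 = "AGATCGGAAGAGC"


@dataclass
class RunConfig:
    """Flat, namespaced parameter document for a pipeline run.

    Attributes use ``<stage>_<name>`` keys. Unknown keys are rejected by
    :meth:`from_dict`.
    """

    # ribo_caller
    ribo_adapter3: str = DEFAULT_ADAPTER3
    ribo_min_overlap: int = 6
    ribo_min_len: int = 24
    ribo_min_cov: float = 0.5
    ribo_min_fold: float = 4.0

    # proteoform_db
    digest_max_missed: int = 5
    digest_suppress_before_p: bool = True
    uniqueness_collapse_il: bool = False

    # conservation_screen
    align_match: float = 1.0
    align_mismatch: float = -1.0
    align_gap: float = -2.0
    conserve_stop2_fraction: float = 0.8
    conserve_isr_identity: float = 0.5
    conserve_stop2_slack_codons: int = 0

    # codon_context
    codon_window: int = 5
    codon_rare_threshold: float = 0.3

    # transcript_topology
    topology_max_scan_nt: int | None = None  # None: scan to transcript end

    # reporter_quant
    reporter_subtract_background: bool = False

    # synthetic_data
    seed: int = 0

    extras: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)} - {"extras"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extras")
        return d

    def dump_json(self, path) -> None:
        """Write the fully resolved configuration next to the results."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


DEFAULTS = RunConfig()
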