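"""Score bundle attached to estimated supertrees."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScoreReport:
    """The (MP score, ML log-likelihood, alpha, sizes) bundle for a supertree."""

    mp_score: int | None = None
    log_likelihood: float | None = None
    alpha: float | None = None
    ncol: int | None = None
    ntax: int | None = None
    resolution: float | None = None
    wall_time: float | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mp_score": self.mp_score,
            "log_likelihood": self.log_likelihood,
            "alpha": self.alpha,
            "ncol": self.ncol,
            "ntax": self.ntax,
            "resolution": self.resolution,
            "wall_time": self.wall_time,
            "notes": list(self.notes),
        }
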