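"""The activator/repressor screen: intersect ripening trajectories,
ethylene responses and EAR-motif flags.

A candidate *activator* of ethylene-regulated ripening is upregulated with
ripening AND induced by exogenous ethylene.  A candidate *repressor* is
downregulated on both axes AND carries an EAR repression motif; a
down/down gene without the motif is reported as ``other`` with the
combination recorded, never silently dropped.

The ripening direction rule operationalizes "up/downregulated with
ripening" over the five stage means (YF young fruit, WM white mature =
ripening onset, BR beginning red, HR half red, FR fully red):

* up:   mean(HR, FR) >= fold x mean(YF, WM)  and  FR > WM
* down: mean(YF, WM) >= fold x mean(HR, FR)  and  FR < WM
* otherwise none

with fold defaulting to 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import config

STAGES = ("YF", "WM", "BR", "HR", "FR")


@dataclass
class CandidateCall:
    gene_id: str
    ripening_direction: str  # up | down | none
    ethylene_direction: str  # up | down | none
    has_ear: bool
    verdict: str  # activator | repressor | other
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == "activator" and not (
            self.ripening_direction == "up" and self.ethylene_direction == "up"
        ):
            raise ValueError("activator requires ripening up AND ethylene up")
        if self.verdict == "repressor" and not (
            self.ripening_direction == "down"
            and self.ethylene_direction == "down"
            and self.has_ear
        ):
            raise ValueError("repressor requires down/down AND an EAR motif")


def call_ripening_direction(
    stage_means: tuple[float, float, float, float, float] | list[float],
    fold: float = config.RIPENING_FOLD,
) -> str:
    """Classify a five-stage trajectory (YF, WM, BR, HR, FR) as up/down/none."""
    if len(stage_means) != len(STAGES):
        raise ValueError(f"expected {len(STAGES)} stage means")
    yf, wm, _br, hr, fr = (float(x) for x in stage_means)
    if min(yf, wm, _br, hr, fr) < 0:
        raise ValueError("negative stage mean")
    early = (yf + wm) / 2.0
    late = (hr + fr) / 2.0
    if late >= fold * early and fr > wm:
        return "up"
    if early >= fold * late and fr < wm:
        return "down"
    return "none"


def call_candidates(
    ripening: dict[str, str],
    ethylene: dict[str, str],
    ear_flags: dict[str, bool],
) -> list[CandidateCall]:
    """Combine the three per-gene calls into verdicts.

    All three inputs must cover the same gene set.  Verdicts partition the
    genes: each gene is exactly one of activator, repressor or other.
    """
    genes = set(ripening)
    if set(ethylene) != genes or set(ear_flags) != genes:
        raise ValueError("ripening, ethylene and EAR inputs cover different genes")
    calls = []
    for gene in sorted(genes):
        rip, eth, ear = ripening[gene], ethylene[gene], ear_flags[gene]
        ev = [f"ripening={rip}", f"ethylene={eth}", f"EAR={'yes' if ear else 'no'}"]
        if rip == "up" and eth == "up":
            verdict = "activator"
        elif rip == "down" and eth == "down" and ear:
            verdict = "repressor"
        else:
            verdict = "other"
            if rip == "down" and eth == "down":
                ev.append("down/down without EAR motif")
        calls.append(CandidateCall(gene, rip, eth, ear, verdict, ev))
    return calls
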