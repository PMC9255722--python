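"""Synthetic stand-in for the study's per-dog supplementary data.

The published study reports only group-level summaries (stage × agent cell
means and SDs); the underlying per-dog selected-cycle endpoints are not
redistributable here.  This module constructs a *synthetic* per-dog table —
ten dogs, two stages, both agents — whose stage × agent cell means and SDs
reproduce the published Table-2 integers exactly under round-half-even, and
whose pooled per-agent means reproduce the published Table-1 integers.  It
exists to exercise the loader/summarizer machinery against known printed
values; it is not the original data.

Construction: per cell, the five ``al_min`` values are an affine transform
of a fixed zero-mean unit-SD pattern, and the five ``al_diff`` values an
affine transform of a correlated pattern, with the min–diff correlation
chosen so that ``al_max = al_min + al_diff`` attains the published cell SD.
Published cell integers are treated as independently rounded (the printed
stage-1 propofol cells 84/48/37 cannot all be exact, since mean(max) −
min) must equal mean(diff)); the unrounded cell means used here
round back to every printed integer.
"""

from __future__ import annotations

import numpy as np

from .study import SubjectResult

__all__ = ["synthetic_reference_results"]

# base patterns: zero mean, unit SD (ddof=1), mutually orthogonal
_Z = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
_Z = _Z / _Z.std(ddof=1)
_W = np.array([1.0, -0.5, -1.0, -0.5, 1.0])
_W = _W / _W.std(ddof=1)

# (stage, agent) -> (min mean, min SD, diff mean, diff SD, max SD)
# chosen so cell means/SDs round to the published stage-table integers and
# pooled per-agent means round to the published overall-table integers.
_CELLS: dict[tuple[int, str], tuple[float, float, float, float, float]] = {
    (1, "propofol"): (47.6, 20.0, 36.8, 17.0, 32.0),
    (2, "propofol"): (29.6, 11.0, 25.8, 24.0, 29.0),
    (1, "alfaxalone"): (20.7, 7.0, 15.7, 8.0, 9.0),
    (2, "alfaxalone"): (34.4, 10.0, 9.4, 10.0, 19.0),
}

# sequence rule: dogs 1-5 received alfaxalone first, dogs 6-10 propofol first
_SEXES = ["female", "female", "male", "male", "male",
          "female", "female", "female", "male", "male"]


def _cell_values(stage: int, agent: str) -> tuple[np.ndarray, np.ndarray]:
    mu_m, sd_m, mu_d, sd_d, sd_max = _CELLS[(stage, agent)]
    # correlation between min and diff implied by the max SD
    rho = (sd_max**2 - sd_m**2 - sd_d**2) / (2.0 * sd_m * sd_d)
    al_min = mu_m + sd_m * _Z
    al_diff = mu_d + sd_d * (rho * _Z + np.sqrt(1.0 - rho**2) * _W)
    return al_min, al_min + al_diff


def synthetic_reference_results() -> list[SubjectResult]:
    """Synthetic per-dog endpoints consistent with the published summaries.

    Returns 20 :class:`SubjectResult` rows (10 dogs × 2 stages) following
    the study's sequence rule and per-cell sex balance.  All ``al_min`` and
    ``al_max - al_min`` values are strictly positive.
    """
    results: list[SubjectResult] = []
    for stage in (1, 2):
        for agent in ("propofol", "alfaxalone"):
            first_half = (agent == "alfaxalone") == (stage == 1)
            dogs = range(1, 6) if first_half else range(6, 11)
            al_min, al_max = _cell_values(stage, agent)
            for k, dog in enumerate(dogs):
                results.append(
                    SubjectResult(
                        subject_id=f"dog{dog:02d}",
                        sex=_SEXES[dog - 1],
                        stage=stage,
                        agent=agent,
                        al_max=float(al_max[k]),
                        al_min=float(al_min[k]),
                    )
                )
    return sorted(results, key=lambda r: (r.subject_id, r.stage))
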