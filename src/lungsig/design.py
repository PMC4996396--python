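"""Six-run study design of the 16k autoantibody microarray experiment.

The screening cohort (100 lung-cancer cases, 25 per histological subtype,
plus 100 matched controls) is too large to hybridize in one day, so arrays
were processed in six runs: four "pure" runs, each pairing 18 cases of a
single histology with 18 controls, and two mixed runs pairing the remaining
7 + 7 cases of two histologies with 14 controls.  Every run is a processing
batch and therefore a potential batch effect.
"""

from __future__ import annotations

#: Histological subtypes of lung cancer covered by the screening.
HISTOLOGIES = ("SCLC", "SqLC", "LCLC", "AdCa")

#: Cross-run analysis pairs: each histology's dedicated run and the mixed
#: run that carries its remaining cases.
CROSS_RUN_PAIRS = {
    "SCLC": (1, 5),
    "SqLC": (2, 5),
    "LCLC": (3, 6),
    "AdCa": (4, 6),
}


def table2_design() -> dict[int, dict]:
    """Return the six-run layout: run -> {"cases": {histology: n}, "controls": n}.

    Totals: 25 cases per histology, 100 cases, 100 controls, 200 arrays.
    """
    return {
        1: {"cases": {"SCLC": 18}, "controls": 18},
        2: {"cases": {"SqLC": 18}, "controls": 18},
        3: {"cases": {"LCLC": 18}, "controls": 18},
        4: {"cases": {"AdCa": 18}, "controls": 18},
        5: {"cases": {"SCLC": 7, "SqLC": 7}, "controls": 14},
        6: {"cases": {"LCLC": 7, "AdCa": 7}, "controls": 14},
    }


def design_totals(run_design: dict[int, dict]) -> dict:
    """Summarize a run design: per-run totals, per-histology case counts, grand total."""
    per_run = {}
    per_hist: dict[str, int] = {}
    n_controls = 0
    for run, grp in run_design.items():
        n_cases = sum(grp["cases"].values())
        per_run[run] = n_cases + grp["controls"]
        n_controls += grp["controls"]
        for hist, n in grp["cases"].items():
            per_hist[hist] = per_hist.get(hist, 0) + n
    return {
        "per_run": per_run,
        "per_histology": per_hist,
        "controls": n_controls,
        "total": sum(per_run.values()),
    }


def session_of_run(run: int, runs: list[int] | None = None) -> int:
    """Map a run to its processing session (0 or 1).

    The six runs were executed in two blocks of consecutive days; runs 1-3
    form the first session and runs 4-6 the second.  For non-default designs
    the first half of the sorted run labels is session 0.
    """
    if runs is None:
        return 0 if run <= 3 else 1
    runs = sorted(runs)
    half = (len(runs) + 1) // 2
    return 0 if run in runs[:half] else 1
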