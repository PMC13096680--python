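"""Assembled cohesion decompositions and the type I vs type II comparison.

Writes the per-type JSON reports, the cross-type comparison, and the
bead-spring reference cross-check on the overall energy scale.
"""

import json
from dataclasses import asdict
from pathlib import Path

from collagen_cohesion.pipeline import run_scenario
from collagen_cohesion.report import (
    BuehlerReference,
    buehler_reference,
    compare,
    write_report,
)
from collagen_cohesion.scenarios import scenario

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    decomps = {}
    for label in ("typeI", "typeII"):
        sc = scenario(label)
        res = run_scenario(sc)
        decomps[label] = res.decomposition
        write_report(res.decomposition, OUT / f"decomposition_{label}.json", config_echo=asdict(sc))
        write_report(res.decomposition, OUT / f"decomposition_{label}.tsv", format="tsv")
        print(
            f"{label}: total {res.decomposition.total_kcal_mol:.0f} kcal/mol per TC; shares "
            + ", ".join(
                f"{m} {100 * f:.0f}%" for m, f in res.decomposition.fractions.items()
            )
        )
    rec = compare(decomps["typeI"], decomps["typeII"])
    (OUT / "comparison.json").write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    print(
        f"type II cohesion is {100 * rec['reduction']:.1f}% lower than type I "
        f"({rec['total_b']:.0f} vs {rec['total_a']:.0f} kcal/mol)"
    )
    ref = buehler_reference(BuehlerReference())
    print(
        f"bead-spring reference scale: {ref:.0f} kcal/mol — same order as the "
        f"type I decomposition, which additionally resolves solvent screening"
    )


if __name__ == "__main__":
    main()
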