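"""Regenerate the example fixture pack under ``examples/data/``.

One 26-tip base tree, a 25-tree pseudo-posterior, the environment table,
group labels, and raw phenotype tables at three planted effect sizes
(null / moderate / strong), each with its ground-truth record.  Everything
is a pure function of the seed below, so the pack is reproducible with

    python scripts/make_fixtures.py
"""

import json
from pathlib import Path

import pcmkit as pk
from pcmkit.synth import BETA_MODERATE, BETA_NULL, BETA_STRONG

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "examples" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    effects = {"null": BETA_NULL, "moderate": BETA_MODERATE, "strong": BETA_STRONG}
    for name, beta in effects.items():
        cfg = pk.StudyConfig(n_trees=25, shape_env_beta=beta)
        study = pk.generate_study(cfg, seed=SEED)
        if name == "null":  # trees/environment/groups identical across effects
            with open(OUT / "base_tree.nwk", "w") as fh:
                fh.write(study.treeset.median_tree.to_newick() + "\n")
            study.treeset.write(OUT / "pseudo_posterior.nwk", schema="newick")
            study.environment.data.round(6).to_csv(OUT / "environment.csv",
                                                   index_label="species")
            study.groups.to_csv(OUT / "groups.csv", index_label="species")
        study.phenotype.data.round(6).to_csv(OUT / f"phenotype_{name}.csv",
                                             index_label="species")
        with open(OUT / f"truth_{name}.json", "w") as fh:
            json.dump(study.truth, fh, indent=2, default=float)
    print("fixture pack written to", OUT)


if __name__ == "__main__":
    main()
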