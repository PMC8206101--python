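"""Simulate the full 2x2 Wheel-of-Fortune experiment at study scale.

50 subjects play 48 two-wheel gambles in each of the four cells of the
beneficiary (self/partner) x audience (present/absent) design.  The long
trial table goes to scratch/ (it is regenerated deterministically from the
seed); a compact summary of what was generated goes to results/.
"""

import json
from pathlib import Path

import regretchoice as rc
from regretchoice.dataset import write_dataset

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = rc.SimulationConfig(seed=SEED)
    dataset = rc.simulate_dataset(config)
    df = dataset.df

    (ROOT / "scratch").mkdir(exist_ok=True)
    out_csv = ROOT / "scratch" / "simulated_trials.csv"
    write_dataset(dataset, out_csv)

    summary = {
        "seed": SEED,
        "n_rows": len(df),
        "n_subjects": dataset.n_subjects(),
        "trials_per_cell": int(df.groupby(["subject_id", "beneficiary", "audience"]).size().iloc[0]),
        "choice_rate_left_by_cell": {
            f"{b}/{a}": round(float(g["choice"].mean()), 4)
            for (b, a), g in df.groupby(["beneficiary", "audience"])
        },
        "rating_mean_by_cell": {
            f"{b}/{a}": round(float(g["rating"].mean()), 2)
            for (b, a), g in df.groupby(["beneficiary", "audience"])
        },
        "ratings_at_scale_bounds": round(float((df["rating"].abs() == 50).mean()), 4),
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "dataset_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"wrote {out_csv} ({len(df)} rows)")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
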