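"""Regenerate the bundled data files under src/ntcana/data/.

The 96-class table carries the real class-name/CANA-code structure of
the conformer alphabet (per-code class counts and the memberships that
are documented for the canonical classes), but its geometry columns are
synthetic: deterministic, family-anchored stand-ins generated here,
because the reference geometries live in an external database.  The two
count tables are published incidence counts shipped verbatim.
"""

from pathlib import Path

import numpy as np
import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "ntcana" / "data"

# CANA code -> member NtC classes.  Canonical memberships (AA00/AA08 in
# AAA, AA01/AA05 in AAw, BB00/BB01 in BBB, the named AB/IC/OP/ZZ classes)
# are fixed; the remaining slots are filled with the systematically
# numbered names so that the per-code class counts are 6, 5, 3, 5, 8, 2,
# 5, 2, 2, 6, 7, 33, 6, 6 (total 96).
MEMBERSHIP = {
    "AAA": ["AA00", "AA02", "AA03", "AA04", "AA06", "AA08"],
    "AAw": ["AA01", "AA05", "AA07", "AA09", "AA12"],
    "AAu": ["AA10", "AA11", "AA13"],
    "A-B": ["AB01", "AB02", "AB03", "AB04", "AB05"],
    "B-A": ["BA01", "BA02", "BA03", "BA04", "BA05", "BA08", "BA09", "BA10"],
    "BBB": ["BB00", "BB01"],
    "BBw": ["BB02", "BB03", "BB04", "BB05", "BB17"],
    "B12": ["BB07", "BB10"],
    "BB2": ["BB08", "BB11"],
    "miB": ["BB12", "BB13", "BB14", "BB15", "BB16", "BB20"],
    "ICL": [f"IC{i:02d}" for i in range(1, 8)],
    "OPN": [f"OP{i:02d}" for i in range(1, 34)],
    "SYN": ["AAS1", "BBS1", "ABS1", "BAS1", "ZZ1S", "ICS1"],
    "ZZZ": ["ZZ01", "ZZ02", "ZZ03", "ZZ04", "ZZS1", "ZZS2"],
}

# family anchors for the synthetic geometry columns:
# d1 e1 z1 a2 b2 g2 d2 ch1 ch2 mu nn cc
ANCHORS = {
    "AA": [83, 212, 287, 295, 173, 53, 83, 199, 199, 21, 4.8, 5.2],
    "AB": [84, 200, 290, 292, 168, 56, 145, 205, 250, 36, 4.5, 4.8],
    "BA": [140, 185, 265, 288, 175, 50, 84, 250, 200, 48, 3.8, 4.4],
    "BB": [139, 187, 258, 300, 177, 44, 139, 252, 252, 42, 4.3, 4.8],
    "IC": [85, 225, 295, 150, 190, 175, 88, 205, 300, 25, 4.5, 5.4],
    "OP": [84, 235, 160, 165, 140, 190, 85, 200, 65, 185, 11.5, 10.2],
    "ZZ": [147, 264, 75, 65, 185, 180, 95, 205, 60, 3, 4.9, 5.5],
}
ANCHOR_BY_NAME = {
    "AAS1": "AA", "BBS1": "BB", "ABS1": "AB", "BAS1": "BA",
    "ZZ1S": "ZZ", "ICS1": "IC",
}

COLS = ["d1", "e1", "z1", "a2", "b2", "g2", "d2", "ch1", "ch2", "mu", "nn", "cc"]


def synth_geometry():
    rng = np.random.default_rng(20200514)
    rows = []
    for code, names in MEMBERSHIP.items():
        for name in names:
            family = ANCHOR_BY_NAME.get(name, name[:2])
            anchor = np.array(ANCHORS[family], dtype=float)
            means = anchor.copy()
            means[:10] = np.mod(means[:10] + rng.uniform(-25, 25, 10), 360.0)
            means[10:] = np.maximum(means[10:] + rng.uniform(-0.8, 0.8, 2), 2.0)
            sd = np.concatenate([rng.uniform(5, 12, 10), rng.uniform(0.15, 0.35, 2)])
            rows.append([name, code] + [round(v, 1) for v in means[:10]]
                        + [round(v, 2) for v in means[10:]]
                        + [round(v, 1) for v in sd[:10]]
                        + [round(v, 2) for v in sd[10:]])
    cols = ["name", "cana"] + COLS + ["sd_" + c for c in COLS]
    return pd.DataFrame(rows, columns=cols)


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    df = synth_geometry()
    assert len(df) == 96 and df["name"].is_unique
    df.to_csv(DATA / "ntc_classes_synthetic.csv", index=False)

    mapping = df[["name", "cana"]].rename(columns={"name": "ntc"})
    mapping = pd.concat(
        [mapping, pd.DataFrame([{"ntc": "NANT", "cana": "NAN"}])],
        ignore_index=True,
    )
    mapping.to_csv(DATA / "cana_mapping.csv", index=False)

    riboswitch = pd.DataFrame(
        {
            "NtC": ["AA00", "AA01", "AA05", "AA12", "AB04", "IC01",
                    "OP05", "OP15", "NANT", "Rest"],
            "Inside": [766, 29, 21, 23, 19, 14, 22, 33, 460, 390],
            "Outside": [3909, 290, 32, 30, 14, 11, 5, 10, 1374, 1593],
        }
    )
    assert riboswitch["Inside"].sum() == 1777
    assert riboswitch["Outside"].sum() == 7268
    riboswitch.to_csv(DATA / "riboswitch_site_counts.csv", index=False)

    ribosome = pd.DataFrame(
        {
            "NtC": ["AA00", "AA03", "AA04", "AA08", "AA06", "AB05",
                    "OP03", "OP04", "NANT", "Rest"],
            "Xray": [8415, 299, 996, 3109, 176, 425, 66, 147, 6933, 3426],
            "CryoEM": [9768, 96, 732, 4586, 331, 403, 154, 96, 8926, 3829],
        }
    )
    assert ribosome["Xray"].sum() == 23992
    assert ribosome["CryoEM"].sum() == 28921
    ribosome.to_csv(DATA / "ribosome_method_counts.csv", index=False)
    print("wrote", sorted(p.name for p in DATA.glob("*.csv")))


if __name__ == "__main__":
    main()
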