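"""Regenerate the bundled synthetic Drosophila RP registry fixture.

Writes src/ribopara/data/dm_rp_synthetic.fasta and .tsv. The fixture
reproduces the fly ribosomal-protein bookkeeping -- 93 proteins (39 SSU,
54 LSU), 13 paralog pairs, RpS14a/RpS14b sequence-identical -- under the
real gene symbols, with deterministic synthetic sequences built from
tryptic blocks. Each distinguishable pair carries substitutions in six of
its internal tryptic peptides (1-2 residues each), so discriminating
peptide pairs exist for every pair except RpS14.

Run from the repository root:  python scripts/make_registry_fixture.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

SEED = 104729  # fixed; the fixture is frozen, rerunning must reproduce it

# (group_id, canonical symbol, alternative symbol, subunit, identical?)
PAIRS = [
    ("RpS14", "RpS14a", "RpS14b", "SSU", True),
    ("RpS19", "RpS19a", "RpS19b", "SSU", False),
    ("RpS5", "RpS5a", "RpS5b", "SSU", False),
    ("RpS15A", "RpS15Aa", "RpS15Ab", "SSU", False),
    ("RpS10", "RpS10b", "RpS10a", "SSU", False),
    ("RpS28", "RpS28b", "RpS28a", "SSU", False),
    ("RpL22", "RpL22", "RpL22-like", "LSU", False),
    ("RpL37", "RpL37a", "RpL37b", "LSU", False),
    ("RpL24", "RpL24", "RpL24-like", "LSU", False),
    ("RpL7", "RpL7", "RpL7-like", "LSU", False),
    ("RpLP0", "RpLP0", "RpLP0-like", "LSU", False),
    ("RpL10A", "RpL10Aa", "RpL10Ab", "LSU", False),
    ("RpL34", "RpL34a", "RpL34b", "LSU", False),
]

SSU_SINGLETONS = [
    "RpS2", "RpS3", "RpS3A", "RpS4", "RpS6", "RpS7", "RpS8", "RpS9",
    "RpS11", "RpS12", "RpS13", "RpS15", "RpS16", "RpS17", "RpS18",
    "RpS20", "RpS21", "RpS23", "RpS24", "RpS25", "RpS26", "RpS27",
    "RpS27A", "RpS29", "RpS30", "RpSA", "RACK1",
]
LSU_SINGLETONS = [
    "RpL3", "RpL4", "RpL5", "RpL6", "RpL7A", "RpL8", "RpL9", "RpL10",
    "RpL11", "RpL12", "RpL13", "RpL13A", "RpL14", "RpL15", "RpL16",
    "RpL17", "RpL18", "RpL18A", "RpL19", "RpL21", "RpL23", "RpL23A",
    "RpL26", "RpL27", "RpL27A", "RpL28", "RpL29", "RpL30", "RpL31",
    "RpL32", "RpL35", "RpL35A", "RpL36", "RpL36A", "RpL38", "RpL39",
    "RpL40", "RpL41", "RpLP1", "RpLP2",
]

N_BLOCKS = 20        # tryptic blocks per protein (~160 residues)
N_SUB_BLOCKS = 6     # blocks mutated in the alternative paralog
BLOCK_LEN = 8
INTERIOR = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P


def main() -> None:
    rng = np.random.default_rng(SEED)
    used: set[str] = set()

    def new_block() -> str:
        while True:
            body = "".join(rng.choice(INTERIOR, size=BLOCK_LEN - 1))
            tail = "K" if rng.random() < 0.5 else "R"
            block = body + tail
            if block not in used:
                used.add(block)
                return block

    def mutate(block: str, n_subs: int) -> str:
        out = list(block)
        for pos in rng.choice(BLOCK_LEN - 1, size=n_subs, replace=False):
            out[pos] = str(rng.choice([c for c in INTERIOR if c != out[pos]]))
        mutated = "".join(out)
        if mutated in used:
            return mutate(block, n_subs)
        used.add(mutated)
        return mutated

    records = []  # (accession, symbol, subunit, group_id, role, sequence)
    for gid, can, alt, subunit, identical in PAIRS:
        blocks = [new_block() for _ in range(N_BLOCKS)]
        if identical:
            alt_blocks = list(blocks)
        else:
            alt_blocks = list(blocks)
            # mutate interior blocks; alternate 1 and 2 substitutions
            targets = rng.choice(
                np.arange(1, N_BLOCKS - 1), size=N_SUB_BLOCKS, replace=False
            )
            for i, b in enumerate(sorted(targets)):
                alt_blocks[b] = mutate(blocks[b], 1 + (i % 2))
        records.append((can, can, subunit, gid, "canonical", "".join(blocks)))
        records.append((alt, alt, subunit, gid, "alternative", "".join(alt_blocks)))
    for symbol in SSU_SINGLETONS:
        records.append((symbol, symbol, "SSU", "", "none",
                        "".join(new_block() for _ in range(N_BLOCKS))))
    for symbol in LSU_SINGLETONS:
        records.append((symbol, symbol, "LSU", "", "none",
                        "".join(new_block() for _ in range(N_BLOCKS))))

    assert len(records) == 93, len(records)
    assert sum(r[2] == "SSU" for r in records) == 39
    assert sum(r[2] == "LSU" for r in records) == 54

    data = Path(__file__).resolve().parents[1] / "src" / "ribopara" / "data"
    with open(data / "dm_rp_synthetic.fasta", "wt", encoding="utf-8") as fh:
        for acc, _, _, _, _, seq in records:
            fh.write(f">{acc} synthetic ribosomal protein stand-in\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(data / "dm_rp_synthetic.tsv", "wt", encoding="utf-8") as fh:
        fh.write("accession\tgene_symbol\tsubunit\tgroup_id\trole\n")
        for acc, sym, subunit, gid, role, _ in records:
            fh.write(f"{acc}\t{sym}\t{subunit}\t{gid}\t{role}\n")
    print(f"wrote {len(records)} records to {data}")


if __name__ == "__main__":
    main()
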