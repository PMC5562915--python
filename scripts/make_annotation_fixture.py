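"""One-off generator of the packaged synthetic pathway-annotation fixture.

Marginals: 575 genes, 4 modules, 13 subsystems, 30 gene families with
sizes in 4..44 summing to 347; the remaining 228 genes carry family
'none'. Gene symbols are synthetic (family prefix + index).
"""
import numpy as np
import pandas as pd

SUBSYSTEMS = {  # subsystem -> module
    "Translocation": "Entry",
    "Signal peptide processing": "Entry",
    "Dolichol pathway": "Processing",
    "ER glycosylation": "Processing",
    "Protein folding": "Folding and quality control",
    "Disulfide bond formation": "Folding and quality control",
    "ERAD": "Folding and quality control",
    "GPI biosynthesis": "Processing",
    "ER-Golgi trafficking": "Trafficking",
    "Golgi glycosylation": "Processing",
    "Post-Golgi trafficking": "Trafficking",
    "Trafficking regulation": "Trafficking",
    "Exocytosis": "Trafficking",
}
SUBS = list(SUBSYSTEMS)
assert len(SUBS) == 13 and len(set(SUBSYSTEMS.values())) == 4

# 30 families: (name, size, subsystem); sizes within 4..44
FAMILIES = [
    ("RAB", 44, "Post-Golgi trafficking"),
    ("DNAJ", 22, "Protein folding"),
    ("TBC1D", 19, "Trafficking regulation"),
    ("PDI", 17, "Disulfide bond formation"),
    ("SEC", 16, "ER-Golgi trafficking"),
    ("HSPA", 13, "Protein folding"),
    ("GALNT", 20, "Golgi glycosylation"),
    ("ARF", 11, "Trafficking regulation"),
    ("STX", 17, "Exocytosis"),
    ("VPS", 24, "Post-Golgi trafficking"),
    ("TMED", 10, "ER-Golgi trafficking"),
    ("SRP", 9, "Translocation"),
    ("MGAT", 8, "Golgi glycosylation"),
    ("PIGX", 12, "GPI biosynthesis"),
    ("ALG", 13, "Dolichol pathway"),
    ("EDEM", 4, "ERAD"),
    ("DERL", 4, "ERAD"),
    ("UBE2", 9, "ERAD"),
    ("VAMP", 8, "Exocytosis"),
    ("SNAP", 5, "Exocytosis"),
    ("GOLGA", 8, "Post-Golgi trafficking"),
    ("COPA", 7, "ER-Golgi trafficking"),
    ("SPCS", 4, "Signal peptide processing"),
    ("SSR", 4, "Translocation"),
    ("B4GALT", 7, "Golgi glycosylation"),
    ("ST6GAL", 6, "Golgi glycosylation"),
    ("OST", 7, "ER glycosylation"),
    ("CALR", 4, "Protein folding"),
    ("ARL", 10, "Trafficking regulation"),
    ("RABGAP", 5, "Trafficking regulation"),
]
sizes = [s for _, s, _ in FAMILIES]
assert len(FAMILIES) == 30, len(FAMILIES)
assert min(sizes) >= 4 and max(sizes) <= 44
total = sum(sizes)
assert total == 347, total

rng = np.random.default_rng(20260924)
rows = []
for name, size, sub in FAMILIES:
    for j in range(size):
        rows.append((f"{name}{j + 1}", SUBSYSTEMS[sub], sub, name))
# 228 singleton components spread across subsystems, family 'none'
for j in range(575 - total):
    sub = SUBS[j % 13]
    rows.append((f"SPC{j + 1:03d}", SUBSYSTEMS[sub], sub, "none"))

df = pd.DataFrame(rows, columns=["gene", "module", "subsystem", "family"])
df["secretory_client"] = rng.random(len(df)) < 0.12
df["complex_count"] = np.where(rng.random(len(df)) < 0.4,
                               rng.integers(1, 6, len(df)), 0)
assert df.gene.is_unique and len(df) == 575
assert df.subsystem.nunique() == 13 and df.module.nunique() == 4
assert (df.family != "none").sum() == 347
assert df[df.family != "none"].family.nunique() == 30
df.to_csv("src/secpath/data/pathway_annotation_synthetic.tsv",
          sep="\t", index=False)
print("ok", len(df))
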