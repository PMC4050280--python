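"""Relative protein abundance of the fusogen vesicle preparations.

Loads the packaged mass-spectrometry emPAI table (one column per vesicle
preparation) and prints each detected protein's share of the total
detected emPAI. The fusogen itself tops its own preparation; the AFF-1
preparation carries ~17% actin while the EFF-1 preparation carries only
~3%, the observation that ruled out an actin-driven mechanism for the
membrane remodelling seen in the EFF-1 sample.
"""

from memtomo.abundance import load_vesicle_proteomics, relative_abundance

for prep in ("AFF-1", "EFF-1"):
    table = relative_abundance(load_vesicle_proteomics(prep))
    df = table.df.dropna(subset=["empai"])
    print(f"\n{prep} vesicle preparation ({len(df)} detected proteins):")
    for _, row in df.iterrows():
        print(f"  {row['protein'][:48]:<50s} emPAI {row['empai']:>5.2f}  "
              f"{row['relative_abundance_int']:>3.0f}%")
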