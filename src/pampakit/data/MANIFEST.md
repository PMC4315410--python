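# Packaged reference tables

Transcriptions of the published PAMPA study tables for the ten model drugs
on the three synthetic phospholipid membranes (octyl C8, decyl C10, lauryl
C12 chains).  All permeabilities are stored already multiplied by the
printed column scale factor, so every `pe_cm_per_s` / `sd_cm_per_s` value
is in plain cm/s.

## table1_drugs.csv

One row per drug: molecular weight, pKa values (ascending,
semicolon-separated), ionization class, human fraction absorbed (%FA,
percent scale) and water solubility (mg/L; blank for metformin, reported
only as "freely soluble").  Metformin and metoprolol rows carry the salt
(hydrochloride / tartrate) molecular weights as printed.

## table1_permeability.csv

One row per (drug, lipid): effective permeability at 16 h incubation,
pH 7.4 both sides, mean +/- SD of triplicate wells.  Printed scale was
1e-6 cm/s.

## table2_ph_profiles.csv

One row per non-missing (drug, lipid, donor pH) cell of the pH-gradient
assay (acceptor pH 7.4, 16 h incubation); 48 points per lipid.  The cells
printed as dashes (atenolol pH 4.6; famotidine pH 8.2) are absent rows,
not zeros.  Printed scales were 1e-7 (amoxicillin, metformin, ranitidine),
1e-6 (atenolol, chloramphenicol, cimetidine, famotidine, ibuprofen,
norfloxacin) and 1e-5 (metoprolol).

Note: the famotidine C12 / pH 4.98 value (1.2e-6 cm/s) is stored exactly
as printed although it breaks the otherwise monotone basic profile and
disagrees with the C8/C10 values (2.2e-6); it is a suspected misprint in
the source table.
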