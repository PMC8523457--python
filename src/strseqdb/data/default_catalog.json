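{
 "schema_version": 1,
 "loci": [
  {"name": "D1S1656", "is_str": true, "period": 4, "motif": "TAGA", "counted_template": [{"motif": "TAGA", "counted": true}]},
  {"name": "TPOX", "is_str": true, "period": 4, "motif": "AATG", "counted_template": [{"motif": "AATG", "counted": true}]},
  {"name": "D2S1338", "is_str": true, "period": 4, "motif": "TGCC", "counted_template": [{"motif": "TGCC", "counted": true}, {"motif": "TTCC", "counted": true}]},
  {"name": "D2S441", "is_str": true, "period": 4, "motif": "TCTA", "counted_template": [{"motif": "TCTA", "counted": true}]},
  {"name": "D3S1358", "is_str": true, "period": 4, "motif": "TCTA", "counted_template": [{"motif": "TCTG", "counted": true}, {"motif": "TCTA", "counted": true}]},
  {"name": "FGA", "is_str": true, "period": 4, "motif": "TTTC", "counted_template": [{"motif": "TTTC", "counted": true}]},
  {"name": "D5S818", "is_str": true, "period": 4, "motif": "AGAT", "counted_template": [{"motif": "AGAT", "counted": true}]},
  {"name": "CSF1PO", "is_str": true, "period": 4, "motif": "AGAT", "counted_template": [{"motif": "AGAT", "counted": true}]},
  {"name": "D7S820", "is_str": true, "period": 4, "motif": "GATA", "counted_template": [{"motif": "GATA", "counted": true}]},
  {"name": "D8S1179", "is_str": true, "period": 4, "motif": "TCTA", "counted_template": [{"motif": "TCTA", "counted": true}]},
  {"name": "D10S1248", "is_str": true, "period": 4, "motif": "GGAA", "counted_template": [{"motif": "GGAA", "counted": true}]},
  {"name": "TH01", "is_str": true, "period": 4, "motif": "AATG", "counted_template": [{"motif": "AATG", "counted": true}]},
  {"name": "vWA", "is_str": true, "period": 4, "motif": "TCTA", "counted_template": [{"motif": "TCTA", "counted": true}, {"motif": "TCTG", "counted": true}]},
  {"name": "D12S391", "is_str": true, "period": 4, "motif": "AGAT", "counted_template": [{"motif": "AGAT", "counted": true}, {"motif": "AGAC", "counted": true}]},
  {"name": "D13S317", "is_str": true, "period": 4, "motif": "TATC", "counted_template": [{"motif": "TATC", "counted": true}]},
  {"name": "Penta E", "is_str": true, "period": 5, "motif": "AAAGA", "counted_template": [{"motif": "AAAGA", "counted": true}]},
  {"name": "D16S539", "is_str": true, "period": 4, "motif": "GATA", "counted_template": [{"motif": "GATA", "counted": true}]},
  {"name": "D18S51", "is_str": true, "period": 4, "motif": "AGAA", "counted_template": [{"motif": "AGAA", "counted": true}]},
  {"name": "D19S433", "is_str": true, "period": 4, "motif": "AAGG", "counted_template": [{"motif": "AAGG", "counted": true}, {"motif": "TAGG", "counted": false}, {"motif": "AAGG", "counted": true}]},
  {"name": "D21S11", "is_str": true, "period": 4, "motif": "TCTA", "counted_template": [{"motif": "TCTA", "counted": true}, {"motif": "TCTG", "counted": true}, {"motif": "TA", "counted": false}]},
  {"name": "Penta D", "is_str": true, "period": 5, "motif": "AAAGA", "counted_template": [{"motif": "AAAGA", "counted": true}]},
  {"name": "D22S1045", "is_str": true, "period": 3, "motif": "ATT", "counted_template": [{"motif": "ATT", "counted": true}]},
  {"name": "AMEL", "is_str": false}
 ],
 "variants": [
  {"locus": "D2S441", "variant_id": "rs888232687", "kind": "deletion", "region": "3'-flank", "net_length_change": -1,
   "note": "[T/-] deletion of the first base downstream of the repeat block; CE 9.3 vs repeat-count 10"},
  {"locus": "D19S433", "variant_id": "rs745607776", "kind": "deletion", "region": "5'-flank", "net_length_change": -2,
   "note": "[CT/-] deletion in the 5' flanking region; CE 14.2 vs repeat-count 15"},
  {"locus": "Penta D", "variant_id": "rs1190908807", "kind": "deletion", "region": "5'-flank", "net_length_change": -13,
   "note": "13-nucleotide [AAGAAAGAAAAAA/-] deletion; yields length-based allele 2.2 from 5 full repeat units"},
  {"locus": "Penta D", "variant_id": "rs536566765", "kind": "deletion", "region": "3'-flank", "net_length_change": -1,
   "ce_designation_override": "13.3",
   "note": "[A/-] deletion in the 3' flanking region; observed CE 13.3 vs repeat-count 14 (override records the observed mapping; uniform arithmetic would give 13.4)"},
  {"locus": "D19S433", "variant_id": "rs147936416", "kind": "deletion", "region": "repeat-boundary", "net_length_change": -2, "designation_shift": -1,
   "note": "[TC/-] deletion spanning a counted repeat unit / uncounted block border; CE X.2 vs repeat-count X.3"},
  {"locus": "D5S818", "variant_id": "rs182073376", "kind": "SNP", "region": "5'-flank", "net_length_change": 0,
   "note": "A>G transition 36 nt upstream of the repeat, inside a CE primer binding site; causes CE heterozygote imbalance, not a length change"},
  {"locus": "TPOX", "variant_id": "rs149212737", "kind": "SNP", "region": "3'-flank", "net_length_change": 0,
   "note": "G>T transversion in the flanking region; distinguishes isometric allele-8 sequences"}
 ]
}
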