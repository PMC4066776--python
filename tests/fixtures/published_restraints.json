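{
  "description": "Restraint definitions and workflow parameters for the DprA-RecA docking study, as published for the DprA-RecA docking study.",
  "dpra_active": ["E235", "M238", "D243", "V244", "E265", "G266", "A267", "E281"],
  "dpra_passive": ["R217", "L231", "I232", "R236", "E239", "G241", "R242", "F245", "H261", "L262", "I263", "Q264", "K268", "E279", "F280", "F282"],
  "reca_main_active": ["R182", "M183", "S185", "R189", "K229", "F230", "Y231", "R235", "K265", "K267"],
  "reca_main_passive": ["R73", "I74", "Q186", "M188", "K190", "G192", "A193", "G225", "R226", "S233", "V264", "V268", "A269", "P270", "P271"],
  "reca_small_active": ["E335", "I336", "D337", "K338", "Q339", "D348", "G349", "E350"],
  "reca_small_passive": ["E328", "F333", "D334", "V340", "R341", "L346", "I347", "E351", "V352", "S353"],
  "ede_triad": ["E235", "D243", "E265"],
  "rrk_triad": ["R189", "R226", "K267"],
  "top_n": 1000,
  "ligand_rmsd_cutoff": 7.5,
  "interface_rmsd_cutoff": 3.0,
  "discard_fraction": 0.5
}
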