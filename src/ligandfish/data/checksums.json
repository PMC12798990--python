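{
 "ligand_library.csv": "58e8bd810455de87966644d35e91e694e0cb015d8c91df39895d0c6a7dcbbc4a",
 "definite_structures.csv": "34aa47973d4f546d4a230f13c1d777c4595b8e38b173d19b4b38c44784e82578"
}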