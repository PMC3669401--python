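{
  "toy": {
    "seed": 0,
    "manifest": {
      "prior.tsv": "59867b6a00fbb19c1143d7054521475d8861bade454c09228004fb4e1443f38b",
      "ppi.tsv": "0aa8435dd9fc4e3c5d88be719926e46b2a1382e8b9e3b18d9633408970b380a1",
      "expression.tsv": "80809eaef5bfa7e4c94b83a8ca3620e07d8199fadca05ab68266b9de38dd9e8c",
      "gold.tsv": "1be475703b8aca23856f884294d90715d08fb60f4ed7b55de726e435154e1871"
    }
  },
  "table1": {
    "seed": 0,
    "manifest": {
      "truth_regulatory.txt": "757f1507e398f5681495d209deebdbe0f0d464987f3a103e35c6a55c8f881eaa",
      "truth_cooperativity.txt": "a4c8cc8e6722e6e0ead53cdb2788de44f1563fe3c24f796bafae10b9b3d90e59",
      "truth_coregulation.txt": "ed267abce1a8da4ba127052b0613a2d2e52b81c96dd0fbdfbf9ab6cbf9b79982",
      "noisy_regulatory.txt": "449a36cd1660a57a96ca2e572ddb3429ab92bedb4bdb0e268f405b2ccbe4a8f9",
      "noisy_cooperativity.txt": "10033532d1ca253dcafafb72f59ca6405ad3b115a2a2dcc4985ba0af693fb5a3",
      "noisy_coregulation.txt": "b0004f34731012d4aac11a3bd1d6b67ffe39db86bfb194ad50bdf51ea48744f4"
    }
  }
}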