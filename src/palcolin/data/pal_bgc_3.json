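{
 "bgc_id": "pal_bgc_3",
 "starter_monomer": "3-methylcrotonic acid",
 "tailoring": [
  {
   "enzyme": "CT",
   "target": "default"
  }
 ],
 "trans_er_modules": [
  9,
  13
 ],
 "genes": [
  {
   "gene_id": "palA",
   "trans_acting": false,
   "domains": [
    {
     "kind": "ACP"
    },
    {
     "kind": "ACP_beta"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "CARRIER_UNRESOLVED",
     "attrs": {
      "clade": "PCP"
     }
    },
    {
     "kind": "KS"
    },
    {
     "kind": "cMT"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "C"
    },
    {
     "kind": "A",
     "attrs": {
      "adenylation_substrate": "glycine"
     }
    }
   ]
  },
  {
   "gene_id": "palB",
   "trans_acting": false,
   "domains": [
    {
     "kind": "ACP",
     "attrs": {
      "ppant_terminal": "I"
     }
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH",
     "attrs": {
      "shift": true
     }
    },
    {
     "kind": "cMT"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH",
     "attrs": {
      "shift": true
     }
    }
   ]
  },
  {
   "gene_id": "palC",
   "trans_acting": false,
   "domains": [
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "cMT"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "A"
     }
    },
    {
     "kind": "DHt"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "ECH"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "LLM"
    },
    {
     "kind": "ACP"
    }
   ]
  },
  {
   "gene_id": "palD",
   "trans_acting": false,
   "domains": [
    {
     "kind": "KS"
    },
    {
     "kind": "DH"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "KS"
    },
    {
     "kind": "DH"
    },
    {
     "kind": "KR",
     "attrs": {
      "kr_type": "B"
     }
    },
    {
     "kind": "ACP"
    },
    {
     "kind": "C_trunc",
     "attrs": {
      "catalytic_his": true,
      "length": 133
     }
    }
   ]
  },
  {
   "gene_id": "palE",
   "trans_acting": true,
   "domains": [
    {
     "kind": "AT",
     "attrs": {
      "specificity": "malonate"
     }
    }
   ]
  },
  {
   "gene_id": "palF",
   "trans_acting": true,
   "domains": [
    {
     "kind": "AT",
     "attrs": {
      "specificity": "relaxed"
     }
    }
   ]
  },
  {
   "gene_id": "palG",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "polysacc_synt_2"
     }
    }
   ]
  },
  {
   "gene_id": "palH",
   "trans_acting": true,
   "domains": [
    {
     "kind": "LO"
    }
   ]
  },
  {
   "gene_id": "palI",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "ABC_transporter"
     }
    }
   ]
  },
  {
   "gene_id": "palJ",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "Band7"
     }
    }
   ]
  },
  {
   "gene_id": "palK",
   "trans_acting": true,
   "domains": [
    {
     "kind": "ACP"
    }
   ]
  },
  {
   "gene_id": "palL",
   "trans_acting": true,
   "domains": [
    {
     "kind": "HCS"
    }
   ]
  },
  {
   "gene_id": "palM",
   "trans_acting": true,
   "domains": [
    {
     "kind": "KS",
     "attrs": {
      "free": true
     }
    }
   ]
  },
  {
   "gene_id": "palN",
   "trans_acting": true,
   "domains": [
    {
     "kind": "ECH"
    }
   ]
  },
  {
   "gene_id": "palO",
   "trans_acting": true,
   "domains": [
    {
     "kind": "ECH"
    }
   ]
  },
  {
   "gene_id": "palP",
   "trans_acting": true,
   "domains": [
    {
     "kind": "GTF"
    }
   ]
  },
  {
   "gene_id": "palQ",
   "trans_acting": true,
   "domains": [
    {
     "kind": "CT"
    }
   ]
  },
  {
   "gene_id": "palR",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "PPTase"
     }
    }
   ]
  },
  {
   "gene_id": "palS",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "NMO"
     }
    }
   ]
  },
  {
   "gene_id": "hyp1",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  },
  {
   "gene_id": "hyp2",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  },
  {
   "gene_id": "hyp3",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  },
  {
   "gene_id": "hyp4",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  },
  {
   "gene_id": "hyp5",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  },
  {
   "gene_id": "hyp6",
   "trans_acting": true,
   "domains": [
    {
     "kind": "OTHER",
     "attrs": {
      "annotation": "hypothetical"
     }
    }
   ]
  }
 ]
}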