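{
 "bgc_id": "pal_bgc_2",
 "starter_monomer": null,
 "tailoring": [
  {
   "enzyme": "CT",
   "target": "default"
  }
 ],
 "trans_er_modules": [
  3
 ],
 "genes": [
  {
   "gene_id": "palB2",
   "trans_acting": false,
   "domains": [
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
      "catalytic_his": true
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
  }
 ]
}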