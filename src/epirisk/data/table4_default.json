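{
 "p_levels": 5,
 "l_levels": 5,
 "states": [
  {
   "index": 1,
   "label": "S1",
   "description": "risk disappearance state"
  },
  {
   "index": 2,
   "label": "S2",
   "description": "risk potential state"
  },
  {
   "index": 3,
   "label": "S3",
   "description": "risk critical state"
  },
  {
   "index": 4,
   "label": "S4",
   "description": "risk outbreak state"
  }
 ],
 "cells": [
  {
   "p": 1,
   "l": 1,
   "state": 1
  },
  {
   "p": 1,
   "l": 2,
   "state": 1
  },
  {
   "p": 1,
   "l": 3,
   "state": 1
  },
  {
   "p": 1,
   "l": 4,
   "state": 2
  },
  {
   "p": 1,
   "l": 5,
   "state": 2
  },
  {
   "p": 2,
   "l": 1,
   "state": 1
  },
  {
   "p": 2,
   "l": 2,
   "state": 1
  },
  {
   "p": 2,
   "l": 3,
   "state": 2
  },
  {
   "p": 2,
   "l": 4,
   "state": 2
  },
  {
   "p": 2,
   "l": 5,
   "state": 3
  },
  {
   "p": 3,
   "l": 1,
   "state": 1
  },
  {
   "p": 3,
   "l": 2,
   "state": 2
  },
  {
   "p": 3,
   "l": 3,
   "state": 2
  },
  {
   "p": 3,
   "l": 4,
   "state": 3
  },
  {
   "p": 3,
   "l": 5,
   "state": 4
  },
  {
   "p": 4,
   "l": 1,
   "state": 2
  },
  {
   "p": 4,
   "l": 2,
   "state": 2
  },
  {
   "p": 4,
   "l": 3,
   "state": 3
  },
  {
   "p": 4,
   "l": 4,
   "state": 4
  },
  {
   "p": 4,
   "l": 5,
   "state": 4
  },
  {
   "p": 5,
   "l": 1,
   "state": 2
  },
  {
   "p": 5,
   "l": 2,
   "state": 3
  },
  {
   "p": 5,
   "l": 3,
   "state": 4
  },
  {
   "p": 5,
   "l": 4,
   "state": 4
  },
  {
   "p": 5,
   "l": 5,
   "state": 4
  }
 ]
}
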