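{
 "neighborhoods": [
  {
   "id": "n00",
   "population": 1238,
   "demand": 74280,
   "x": 6.146345501329262,
   "y": 6.506575505714656
  },
  {
   "id": "n01",
   "population": 23,
   "demand": 1380,
   "x": 3.121821013431323,
   "y": 2.884696458762509
  },
  {
   "id": "n02",
   "population": 183,
   "demand": 10980,
   "x": 6.639141125684282,
   "y": 4.448061468911632
  },
  {
   "id": "n03",
   "population": 1209,
   "demand": 72540,
   "x": 8.175042698371831,
   "y": 6.710183154585046
  },
  {
   "id": "n04",
   "population": 961,
   "demand": 57660,
   "x": 6.552932296700034,
   "y": 6.375196730741511
  },
  {
   "id": "n05",
   "population": 747,
   "demand": 44820,
   "x": 7.611855166072322,
   "y": 5.724516938221684
  },
  {
   "id": "n06",
   "population": 689,
   "demand": 41340,
   "x": 7.954135781268009,
   "y": 5.053354224799625
  },
  {
   "id": "n07",
   "population": 287,
   "demand": 17220,
   "x": 5.595004108817423,
   "y": 4.77509064851114
  },
  {
   "id": "n08",
   "population": 369,
   "demand": 22140,
   "x": 7.0757913879272865,
   "y": 6.064591642727111
  },
  {
   "id": "n09",
   "population": 1428,
   "demand": 85680,
   "x": 4.4479192975289354,
   "y": 9.603383896881073
  },
  {
   "id": "n10",
   "population": 589,
   "demand": 35340,
   "x": 5.345314748269096,
   "y": 5.790660407476707
  },
  {
   "id": "n11",
   "population": 277,
   "demand": 16620,
   "x": 6.709496590429192,
   "y": 9.145771641200385
  }
 ],
 "markets": [
  {
   "id": "m00",
   "capacity": 480000,
   "x": 4.299022967931348,
   "y": 3.6124624542236137
  }
 ],
 "candidates": [
  {
   "id": "c00",
   "capacity": 40000,
   "cost": 10606,
   "x": 6.66399529255853,
   "y": 3.917966245251968
  },
  {
   "id": "c01",
   "capacity": 40000,
   "cost": 11437,
   "x": 5.63754558446321,
   "y": 9.510276414741712
  },
  {
   "id": "c02",
   "capacity": 40000,
   "cost": 11778,
   "x": 8.946459068839655,
   "y": 7.92559977160942
  },
  {
   "id": "c03",
   "capacity": 40000,
   "cost": 9882,
   "x": 6.242507988458733,
   "y": 8.655833548574545
  },
  {
   "id": "c04",
   "capacity": 40000,
   "cost": 9158,
   "x": 6.942353756880679,
   "y": 5.2624987160829715
  },
  {
   "id": "c05",
   "capacity": 40000,
   "cost": 12689,
   "x": 6.189501574361968,
   "y": 3.8298013442257304
  }
 ],
 "fastfood": [
  {
   "id": "f00",
   "x": 6.660368676503815,
   "y": 6.20481635522189
  },
  {
   "id": "f01",
   "x": 5.8484402107903595,
   "y": 5.755085474177498
  },
  {
   "id": "f02",
   "x": 4.812751580706309,
   "y": 5.864562340991024
  },
  {
   "id": "f03",
   "x": 6.4622870904707295,
   "y": 5.971057624005604
  },
  {
   "id": "f04",
   "x": 6.719447217518672,
   "y": 5.9510056985357505
  },
  {
   "id": "f05",
   "x": 7.1366998565605115,
   "y": 6.025640357631175
  },
  {
   "id": "f06",
   "x": 5.161593910580459,
   "y": 6.221210557536458
  },
  {
   "id": "f07",
   "x": 5.404691939827101,
   "y": 6.078758012111337
  }
 ],
 "d_market": [
  [
   4.463468339339455
  ],
  [
   1.799196142183951
  ],
  [
   3.2302786276808146
  ],
  [
   6.450332565463401
  ],
  [
   4.635153225836009
  ],
  [
   5.107466781560395
  ],
  [
   5.107530883500976
  ],
  [
   2.2633710977891037
  ],
  [
   4.815860556745998
  ],
  [
   7.790602906381018
  ],
  [
   3.1413963542089887
  ],
  [
   7.846218213726445
  ]
 ],
 "d_candidate": [
  [
   3.4318176036052357,
   3.960435972924565,
   4.080895649276049,
   2.79683069495666,
   1.920023953073666,
   3.480258637723616
  ],
  [
   4.796743705619066,
   9.213247743381276,
   10.01397642394416,
   8.529100817455008,
   5.850059802393557,
   4.1729569232931905
  ],
  [
   0.6898808317605921,
   6.708455209532604,
   5.42537657369859,
   5.494351798592085,
   1.1297635241554096,
   0.9938168897407766
  ],
  [
   4.127318718978865,
   4.912454522746367,
   1.8714224805116522,
   3.5649986682324535,
   2.471816684004912,
   4.547951654240131
  ],
  [
   3.1976608849121764,
   4.245780388099486,
   3.7073301440197985,
   2.992166130538966,
   1.5325373234774853,
   3.3425726712433836
  ],
  [
   2.652147758117359,
   5.550539217353584,
   3.34631545677481,
   4.206003044389939,
   1.0574786649863457,
   3.079940323797022
  ],
  [
   2.2341733376257866,
   6.529928022164576,
   3.9504816136898335,
   5.184951358989745,
   1.343123538045427,
   2.791525793433882
  ],
  [
   1.7812392947461733,
   6.15598991959766,
   5.979711461399576,
   5.1147073400750696,
   1.8626408431081887,
   1.4516984838514595
  ],
  [
   2.8414968748717984,
   4.8539455880114,
   3.430312743703932,
   3.538507307747154,
   1.0570516272891766,
   3.12535717272768
  ],
  [
   7.932659938806892,
   1.551243598792323,
   6.241600371714101,
   2.638199460313667,
   6.508507797340113,
   7.839696786204532
  ],
  [
   2.9775113849101547,
   4.8504012364216695,
   5.442360608716649,
   3.9030695737356043,
   2.186740803275094,
   2.7753156993299
  ],
  [
   6.796404429399847,
   1.4718978037291737,
   3.312531762980695,
   0.8798970930567547,
   5.057322662224651,
   6.943744679597395
  ]
 ],
 "d_fastfood": [
  [
   0.7748680610873503,
   1.0508993111026517,
   1.9241113965863845,
   0.8083015817448105,
   1.0376438335451188,
   1.431240586988441,
   1.3328448353170985,
   1.1130595240938157
  ],
  [
   6.307949866421349,
   5.146684295427976,
   4.454060079569021,
   5.912404981354903,
   6.145187682443105,
   6.626784996092063,
   5.083814480044681,
   5.103808753827634
  ],
  [
   2.283948071593575,
   1.9858620977531345,
   3.004708504851182,
   1.9931991718245192,
   1.9566146323461322,
   2.150437288311386,
   3.0004956012407473,
   2.6588213280153115
  ],
  [
   2.075784131495966,
   3.269516983781379,
   4.507097585290764,
   2.425062218742689,
   2.134182175231209,
   1.6167917118861597,
   3.9687208994141536,
   3.693817043479582
  ],
  [
   0.2618525562872323,
   1.2200948928953141,
   2.357619588332214,
   0.5384338408751334,
   0.592413937727459,
   0.8845487183063975,
   1.819783744329416,
   1.5416552125824297
  ],
  [
   1.3855914902905604,
   2.2927838516605403,
   3.643386224104333,
   1.5284202722483342,
   1.1969104343148111,
   0.7312981063610637,
   3.250126038180527,
   2.906032528253307
  ],
  [
   2.2515528479232727,
   2.885408668348669,
   4.2177644650454065,
   2.2769647683483654,
   1.9844635270027835,
   1.6513284553707648,
   3.934981790013994,
   3.5723084187683405
  ],
  [
   2.317910301733842,
   1.3159055134150637,
   1.7435843028378486,
   1.9205346528216074,
   2.1151077942247736,
   2.5806556526522395,
   1.962572585448417,
   1.7127307917544223
  ],
  [
   0.569985884545869,
   1.6455067963574406,
   2.9534217282920223,
   0.8067713859938276,
   0.48621205179269095,
   0.09398778981101423,
   2.4967722520925606,
   2.172507341062682
  ],
  [
   5.2718476046515415,
   5.323791194998598,
   4.883553294944747,
   5.399535838457578,
   5.591466932355006,
   5.818104901004039,
   4.493644760844174,
   4.747830932449049
  ],
  [
   1.792346911632591,
   0.6556960909513256,
   0.6989661574386921,
   1.4708799827203352,
   1.7984928711685693,
   2.348750039825227,
   0.6085427303653829,
   0.3823986641428834
  ],
  [
   3.823775269655246,
   4.547802612795049,
   4.9269787512465,
   4.139621667623049,
   4.153215870783502,
   4.094013915320498,
   4.301617347328311,
   4.332938765267042
  ]
 ]
}
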