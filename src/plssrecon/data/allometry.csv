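genus,group,beta0,beta1
Poplar,"Aspen, Alder, Poplar, Willow",-2.20,2.38
Willow,"Aspen, Alder, Poplar, Willow",-2.20,2.38
Alder,"Aspen, Alder, Poplar, Willow",-2.20,2.38
Birch,"Soft Maple, Birch",-1.91,2.36
Ash,Mixed Hardwood,-2.48,2.48
Elm,Mixed Hardwood,-2.48,2.48
Maple,Mixed Hardwood,-2.48,2.48
Basswood,Mixed Hardwood,-2.48,2.48
Ironwood,Mixed Hardwood,-2.48,2.48
Walnut,Mixed Hardwood,-2.48,2.48
Hackberry,Mixed Hardwood,-2.48,2.48
Cherry,Mixed Hardwood,-2.48,2.48
Dogwood,Mixed Hardwood,-2.48,2.48
Buckeye,Mixed Hardwood,-2.48,2.48
Locust,Mixed Hardwood,-2.48,2.48
Sycamore,Mixed Hardwood,-2.48,2.48
Chestnut,Mixed Hardwood,-2.48,2.48
Tupelo,Mixed Hardwood,-2.48,2.48
Oak,"Hard Maple, Oak, Hickory, Beech",-2.01,2.43
Hickory,"Hard Maple, Oak, Hickory, Beech",-2.01,2.43
Beech,"Hard Maple, Oak, Hickory, Beech",-2.01,2.43
OtherHardwood,"Hard Maple, Oak, Hickory, Beech",-2.01,2.43
Tamarack,Cedar and Larch,-2.03,2.26
Cedar,Cedar and Larch,-2.03,2.26
Fir,Fir and Hemlock,-2.54,2.43
Hemlock,Fir and Hemlock,-2.54,2.43
Pine,Pine,-2.54,2.43
Spruce,Spruce,-2.08,2.33
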