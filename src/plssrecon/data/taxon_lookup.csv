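raw_name,genus
oak,Oak
white oak,Oak
black oak,Oak
red oak,Oak
bur oak,Oak
burr oak,Oak
pin oak,Oak
jack oak,Oak
swamp oak,Oak
pine,Pine
white pine,Pine
norway pine,Pine
red pine,Pine
jack pine,Pine
yellow pine,Pine
maple,Maple
sugar maple,Maple
hard maple,Maple
soft maple,Maple
red maple,Maple
white maple,Maple
birch,Birch
white birch,Birch
yellow birch,Birch
paper birch,Birch
black birch,Birch
tamarack,Tamarack
tamarac,Tamarack
larch,Tamarack
hackmatack,Tamarack
cedar,Cedar
white cedar,Cedar
red cedar,Cedar
juniper,Cedar
fir,Fir
balsam,Fir
balsam fir,Fir
hemlock,Hemlock
spruce,Spruce
black spruce,Spruce
white spruce,Spruce
ash,Ash
white ash,Ash
black ash,Ash
brown ash,Ash
green ash,Ash
swamp ash,Ash
elm,Elm
white elm,Elm
red elm,Elm
slippery elm,Elm
basswood,Basswood
linden,Basswood
lynn,Basswood
ironwood,Ironwood
hornbeam,Ironwood
blue beech,Ironwood
walnut,Walnut
black walnut,Walnut
butternut,Walnut
hackberry,Hackberry
cherry,Cherry
black cherry,Cherry
choke cherry,Cherry
wild cherry,Cherry
dogwood,Dogwood
buckeye,Buckeye
poplar,Poplar
aspen,Poplar
popple,Poplar
cottonwood,Poplar
balm of gilead,Poplar
willow,Willow
alder,Alder
hickory,Hickory
shagbark hickory,Hickory
beech,Beech
locust,Locust
black locust,Locust
honey locust,Locust
sycamore,Sycamore
buttonwood,Sycamore
chestnut,Chestnut
tupelo,Tupelo
black gum,Tupelo
pepperidge,Tupelo
otherhardwood,OtherHardwood
other hardwood,OtherHardwood
hawthorn,OtherHardwood
thorn,OtherHardwood
thorn apple,OtherHardwood
white thorn,OtherHardwood
may cherry,OtherHardwood
crab apple,OtherHardwood
mountain ash,OtherHardwood
box elder,OtherHardwood
mulberry,OtherHardwood
no tree,NonTree
none,NonTree
rock,NonTree
stone,NonTree
mound,NonTree
post,NonTree
stake,NonTree
water,Water
lake,Water
river,Water
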