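group_id,name
1,Milk and milk products
2,Cheese and cheese products
3,"Ice cream, fruit ice, and other edible ices"
4,Cereals and cereal products
5,Vegetables and vegetable products
6,Fruit and fruit products
7,Meat and meat products
8,Fish and fish products
9,Poultry and poultry products
10,Eggs and egg products
11,"Fats, oils, and their products"
12,"Sugar, honey, and their products"
13,Beverages
14,Spices and other ingredients
17,Other foods
25,Potatoes and their products
26,Juice
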